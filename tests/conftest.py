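import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

import ginpipe as gp
from ginpipe.enrichment import GODag

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library1536():
    return gp.generate_library(1536, 1536, seed=0)


@pytest.fixture(scope="session")
def screen50(library1536):
    """One synthetic screen with 50 planted hits (effect 0.5, CV 0.10)."""
    rng = np.random.default_rng(0)
    hits = set(rng.choice(library1536.genes, 50, replace=False))
    truth = gp.SyntheticTruth(
        {("S288C", "atorvastatin"): hits}, effect_size=0.5, noise_cv=0.10
    )
    control, treated = gp.generate_screen_pair(
        library1536, truth, "S288C", "atorvastatin", inhibition=0.4, seed=11
    )
    control = [gp.normalize_plate(p) for p in control]
    treated = [gp.normalize_plate(p) for p in treated]
    ratios = gp.compute_ratios(treated, control)
    profile = gp.score_profile(ratios, background="S288C", probe="atorvastatin")
    return {"hits": hits, "truth": truth, "ratios": ratios, "profile": profile}


@pytest.fixture
def twin_triangles():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return g


@pytest.fixture(scope="session")
def toy_dag():
    """Five-term DAG with hand-computable information contents.

    Root R; A, B below R; C below A; D below A and B.  The 10-gene corpus
    gives propagated counts R:10, A:6, B:4, C:3, D:2.
    """
    terms = {
        "R": ("root", "bp"),
        "A": ("a", "bp"),
        "B": ("b", "bp"),
        "C": ("c", "bp"),
        "D": ("d", "bp"),
    }
    parents = {"R": [], "A": ["R"], "B": ["R"], "C": ["A"], "D": ["A", "B"]}
    dag = GODag(terms, parents)
    ann = {
        "g1": {"C", "A", "R"},
        "g2": {"C", "A", "R"},
        "g3": {"C", "A", "R"},
        "g4": {"D", "A", "B", "R"},
        "g5": {"D", "A", "B", "R"},
        "g6": {"A", "R"},
        "g7": {"B", "R"},
        "g8": {"B", "R"},
        "g9": {"R"},
        "g10": {"R"},
    }
    dag.set_corpus(ann)
    return dag, ann


def random_weighted_graph(rng, n_min=2, n_max=8, p=None):
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(0.25, 0.8)) if p is None else p
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(10**6)))
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.normal(0.3, 0.2))
    return g
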