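"""GO enrichment, two-stage FDR, Lin semantic similarity and SAFE scoring.

Over-representation of GO terms in a study set is tested with the one-sided
hypergeometric tail and corrected with the two-stage Benjamini-Krieger-
Yekutieli (BKY) linear step-up FDR.  Term redundancy is quantified with Lin
similarity on an information-content-annotated DAG, and a REVIGO-style
'uniqueness' (one minus mean Lin similarity to the other terms of a result
set).  SAFE-style enrichment scores local network-map neighborhoods instead
of discrete communities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GODag",
    "SafeConfig",
    "hypergeom_enrich",
    "bky_fdr",
    "lin_similarity",
    "uniqueness",
    "uniqueness_table",
    "safe_enrichment",
]


class GODag:
    """A rooted is_a DAG of ontology terms with information content.

    Terms are (id, name, namespace); every non-root term has at least one
    parent in the same namespace.  Information content is estimated from an
    annotation corpus: IC(t) = -ln(n_t / N) where n_t counts genes annotated
    to t (annotations are expected to already obey the true-path rule) and N
    is the root's count.  IC(root) = 0 and IC never decreases root-to-leaf.
    """

    def __init__(self, terms: Mapping[str, tuple[str, str]],
                 parents: Mapping[str, Iterable[str]]):
        self.terms = {t: tuple(v) for t, v in terms.items()}
        self.parents = {t: set(parents.get(t, ())) for t in self.terms}
        for t, ps in self.parents.items():
            missing = ps - set(self.terms)
            if missing:
                raise ValueError(f"term {t} has unknown parents {missing}")
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((t, p) for t, ps in self.parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("term graph is cyclic")
        self._child_to_parent = g
        self.roots = {t for t, ps in self.parents.items() if not ps}
        self.ic: dict[str, float] = {}

    def namespace(self, term: str) -> str:
        return self.terms[term][1]

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of ``term`` including ``term`` itself."""
        return nx.descendants(self._child_to_parent, term) | {term}

    def set_corpus(self, annotations: Mapping[str, Iterable[str]]) -> None:
        """Estimate IC from a gene -> terms corpus (true-path-propagated)."""
        counts: dict[str, int] = {t: 0 for t in self.terms}
        for terms in annotations.values():
            for t in set(terms):
                if t in counts:
                    counts[t] += 1
        n_root: dict[str, int] = {}
        for t, c in counts.items():
            ns = self.namespace(t)
            if t in self.roots:
                n_root[ns] = c
        self.ic = {}
        for t, c in counts.items():
            total = n_root.get(self.namespace(t), 0)
            if c <= 0 or total <= 0:
                self.ic[t] = 0.0
            else:
                self.ic[t] = -math.log(c / total)

    @classmethod
    def from_tsv(cls, path) -> "GODag":
        """Read a (child, parent, namespace, name) term table; empty parent
        marks a root."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        terms: dict[str, tuple[str, str]] = {}
        parents: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            terms[row.child] = (getattr(row, "name", row.child), row.namespace)
            parents.setdefault(row.child, set())
            if row.parent:
                parents[row.child].add(row.parent)
        return cls(terms, parents)

    def to_tsv(self, path) -> None:
        rows = []
        for t, (name, ns) in sorted(self.terms.items()):
            ps = sorted(self.parents[t]) or [""]
            for p in ps:
                rows.append({"child": t, "parent": p, "namespace": ns, "name": name})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SafeConfig:
    """SAFE neighborhood parameters.

    ``radius`` is in the units of the 2D map embedding (edge length = Euclidean
    distance between endpoint coordinates); ``alpha`` is the neighborhood
    enrichment significance threshold.
    """

    radius: float = 7.5
    alpha: float = 0.05

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def _invert_annotations(
    annotations: Mapping[str, Iterable[str]], genes: set[str]
) -> dict[str, set[str]]:
    by_term: dict[str, set[str]] = {}
    for g in genes:
        for t in annotations.get(g, ()):
            by_term.setdefault(t, set()).add(g)
    return by_term


def hypergeom_enrich(
    study: set[str],
    population: set[str],
    annotations: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per GO term.

    Population totals are dataset-restricted (only population genes count
    toward a term).  Terms with zero study overlap are skipped.  Returns a
    DataFrame with p_raw, BKY-adjusted p and the two-stage rejection flag,
    plus coverage = 100 * study_count / population_count.
    """
    if not study:
        raise ValueError("empty study set")
    if not study <= population:
        raise ValueError("study must be a subset of the population")
    by_term = _invert_annotations(annotations, population)
    n_pop, n_study = len(population), len(study)
    rows = []
    for term in sorted(by_term):
        term_genes = by_term[term]
        k = len(term_genes & study)
        if k == 0:
            continue
        K = len(term_genes)
        p = float(stats.hypergeom.sf(k - 1, n_pop, K, n_study))
        rows.append(
            {
                "term": term,
                "study_count": k,
                "population_count": K,
                "coverage": 100.0 * k / K,
                "p_raw": p,
            }
        )
    df = pd.DataFrame(
        rows, columns=["term", "study_count", "population_count", "coverage", "p_raw"]
    )
    if len(df):
        reject, adj = bky_fdr(df["p_raw"].to_numpy(), alpha=alpha)
        df["p_adjusted"] = adj
        df["significant"] = reject
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df.set_index("term")


def _bh_reject(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up rejection flags."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        kmax = np.max(np.nonzero(below)[0])
        reject[order[: kmax + 1]] = True
    return reject


def bky_fdr(p_values: Sequence[float], alpha: float = 0.05):
    """Two-stage Benjamini-Krieger-Yekutieli FDR (TST, 2006 definition 6).

    Stage 1: BH at q' = alpha/(1+alpha); the number of non-rejections
    estimates m0.  Stage 2: BH at q' * m/m0.  Returns (reject flags,
    adjusted p-values).  Adjusted values are the stage-2 BH-adjusted
    p-values scaled by m0/m / (1+alpha); because alpha enters the procedure,
    they can fall below the raw p — the rejection flags, not a monotone
    adjusted-p, define the procedure.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    q1 = alpha / (1.0 + alpha)
    stage1 = _bh_reject(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool), _bh_adjust(p) * 1.0 / (1.0 + alpha)
    m0 = m - r1
    if m0 == 0:
        return np.ones(m, dtype=bool), np.zeros(m)
    q2 = q1 * m / m0
    reject = _bh_reject(p, q2)
    adjusted = _bh_adjust(p) * (m0 / m) / (1.0 + alpha)
    return reject, np.minimum(adjusted, 1.0)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = ranked
    return out


def lin_similarity(t1: str, t2: str, dag: GODag) -> float:
    """Lin similarity: 2*IC(MICA) / (IC(t1)+IC(t2)), in [0, 1].

    MICA is the common ancestor with maximal information content.  Defined as
    0 when both terms carry zero information (e.g. the root against itself).
    """
    if dag.namespace(t1) != dag.namespace(t2):
        raise ValueError("terms from different namespaces are not comparable")
    if not dag.ic:
        raise ValueError("DAG has no IC; call set_corpus first")
    common = dag.ancestors(t1) & dag.ancestors(t2)
    ic_mica = max((dag.ic[a] for a in common), default=0.0)
    denom = dag.ic[t1] + dag.ic[t2]
    if denom <= 0:
        return 0.0
    return 2.0 * ic_mica / denom


def uniqueness(term: str, term_set: Sequence[str], dag: GODag) -> float:
    """1 - mean Lin similarity of ``term`` to the other terms of the set.

    High uniqueness marks a term that is semantically unlike the rest of the
    result set (and therefore survives REVIGO-style redundancy pruning).
    A singleton set gives 1.
    """
    if term not in term_set:
        raise ValueError(f"{term!r} not in term_set")
    others = [t for t in term_set if t != term]
    # duplicates of `term` in the set count as perfectly similar others
    dups = sum(1 for t in term_set if t == term) - 1
    sims = [lin_similarity(term, t, dag) for t in others]
    sims += [1.0] * dups
    if not sims:
        return 1.0
    return 1.0 - float(np.mean(sims))


def uniqueness_table(terms: Sequence[str], dag: GODag) -> pd.Series:
    """Uniqueness of every term of a result set, as a Series."""
    return pd.Series({t: uniqueness(t, list(terms), dag) for t in terms},
                     name="uniqueness")


def safe_enrichment(
    gin: nx.Graph,
    embedding: Mapping[str, tuple[float, float]],
    attributes: Mapping[str, Iterable[str]],
    config: SafeConfig | None = None,
) -> pd.DataFrame:
    """SAFE-style neighborhood enrichment on a 2D network map.

    Each edge gets a length equal to the Euclidean distance between its
    endpoints in the embedding; a node's neighborhood is every node within
    map-weighted shortest-path distance <= radius.  Per (node, attribute),
    the one-sided hypergeometric p of the attribute count in the neighborhood
    is computed and turned into a normalized enrichment score
    min(-log10 p, 16)/16.
    """
    config = config or SafeConfig()
    nodes = sorted(gin.nodes)
    missing = [n for n in nodes if n not in embedding]
    if missing:
        raise KeyError(f"embedding missing coordinates for {missing[:5]}...")

    import igraph as ig

    idx = {n: i for i, n in enumerate(nodes)}
    edges, lengths = [], []
    for u, v in gin.edges:
        xu, yu = embedding[u]
        xv, yv = embedding[v]
        edges.append((idx[u], idx[v]))
        lengths.append(math.hypot(xu - xv, yu - yv))
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    dist = np.asarray(g.distances(weights=lengths))

    by_attr = _invert_annotations(attributes, set(nodes))
    attr_names = sorted(by_attr)
    n = len(nodes)
    member = np.zeros((len(attr_names), n), dtype=bool)
    for ai, a in enumerate(attr_names):
        for gname in by_attr[a]:
            member[ai, idx[gname]] = True
    K = member.sum(axis=1)

    within = dist <= config.radius  # includes self (distance 0)
    sizes = within.sum(axis=1)
    # counts[ni, ai] = attribute genes inside node ni's neighborhood
    counts = within.astype(np.float64) @ member.T.astype(np.float64)
    counts = counts.astype(np.int64)
    p = stats.hypergeom.sf(
        counts - 1, n, K[np.newaxis, :], sizes[:, np.newaxis]
    )
    score = np.minimum(-np.log10(np.maximum(p, 1e-300)), 16.0) / 16.0
    n_attr = len(attr_names)
    return pd.DataFrame(
        {
            "node": np.repeat(nodes, n_attr),
            "attribute": np.tile(attr_names, n),
            "neighborhood_size": np.repeat(sizes, n_attr),
            "attribute_count": counts.ravel(),
            "p": p.ravel(),
            "score": score.ravel(),
            "significant": p.ravel() < config.alpha,
        }
    )
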