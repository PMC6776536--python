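"""Augmented GIN assembly: seed hits + bounded neighborhood of a global GIN.

The primary hits of a screen (seed genes) are expanded with every gene within
a bounded hop distance (default 2, i.e. a path of at most 3 nodes) in the
stringently edge-filtered global network; the augmented GIN is the induced
subgraph on that node set.  Seed centrality can be validated against a
bootstrap null of equally sized random gene sets with a Mann-Whitney rank
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .exceptions import EmptyNetworkError

__all__ = [
    "filter_stringent",
    "build_augmented_gin",
    "node_strength",
    "total_weight",
    "bootstrap_centrality_test",
    "BootstrapResult",
]

DEFAULT_WEIGHT_CUTOFF = 0.12
DEFAULT_P_CUTOFF = 0.05


def filter_stringent(
    gin: nx.Graph,
    weight_cutoff: float = DEFAULT_WEIGHT_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> nx.Graph:
    """Keep edges with |weight| >= weight_cutoff and p < p_cutoff.

    The weight boundary is inclusive (an edge at exactly the cutoff
    survives); the p boundary is strict.  Edges without a 'p' attribute are
    treated as p = 0 (pass).  Nodes are all retained.
    """
    out = nx.Graph()
    out.add_nodes_from(gin.nodes(data=True))
    for u, v, d in gin.edges(data=True):
        if abs(d.get("weight", 0.0)) >= weight_cutoff and d.get("p", 0.0) < p_cutoff:
            out.add_edge(u, v, **d)
    return out


def build_augmented_gin(
    seeds,
    global_gin: nx.Graph,
    hop_bound: int = 2,
    weight_cutoff: float = DEFAULT_WEIGHT_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> nx.Graph:
    """Seeds plus their <= hop_bound neighborhood in the filtered global GIN.

    Node attribute ``provenance`` is 'seed' or 'augmented'.  Seeds absent
    from the global network are dropped with a warning; an empty result
    raises EmptyNetworkError.
    """
    seeds = set(seeds)
    present = seeds & set(global_gin.nodes)
    missing = seeds - present
    if missing:
        warnings.warn(
            f"{len(missing)} seed gene(s) absent from the global GIN; dropped"
        )
    if not present:
        raise EmptyNetworkError("no seed gene is present in the global GIN")

    filtered = filter_stringent(global_gin, weight_cutoff, p_cutoff)
    nodes = set(present)
    if hop_bound > 0:
        dist = nx.multi_source_dijkstra_path_length(
            filtered, present, cutoff=hop_bound, weight=None
        )
        nodes |= set(dist)
    sub = filtered.subgraph(nodes).copy()
    if sub.number_of_nodes() == 0:
        raise EmptyNetworkError("augmented network is empty after filtering")
    nx.set_node_attributes(
        sub, {n: ("seed" if n in present else "augmented") for n in sub.nodes},
        "provenance",
    )
    return sub


def node_strength(gin: nx.Graph) -> dict[str, float]:
    """k_i = sum_j |A_ij|: absolute-weight strength per node.

    Negative interaction scores contribute to connectivity, matching the use
    of negative genetic interactions as edges.
    """
    return {
        n: sum(abs(d.get("weight", 1.0)) for _, _, d in gin.edges(n, data=True))
        for n in gin.nodes
    }


def total_weight(gin: nx.Graph) -> float:
    """m = sum over edges of |weight| (so 2m = sum_ij |A_ij|)."""
    return sum(abs(d.get("weight", 1.0)) for _, _, d in gin.edges(data=True))


@dataclass
class BootstrapResult:
    """Seed-vs-null centrality comparison.

    ``observed`` holds the seed genes' centrality values; ``null`` pools the
    values of ``n_boot`` random gene sets of the same size.  ``included``
    follows the study rule: keep the network when the Mann-Whitney p < 0.05.
    """

    metric: str
    observed: np.ndarray
    null: np.ndarray
    u: float
    p: float
    n_boot: int

    @property
    def included(self) -> bool:
        return self.p < 0.05


def bootstrap_centrality_test(
    gin: nx.Graph,
    seeds,
    metric: str = "BC",
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Mann-Whitney test of seed centrality against a random-gene-set null.

    The null pools the ``metric`` values of ``n_boot`` uniform random node
    sets of size |seeds| drawn (without replacement within a draw) from the
    network.  Two-sided; exact for small samples (scipy's default policy).
    """
    from .centrality import compute_centralities

    seeds = sorted(set(seeds) & set(gin.nodes))
    if len(seeds) < 3:
        raise ValueError("need at least three seed genes present in the network")
    if len(seeds) > gin.number_of_nodes():
        raise ValueError("more seeds than network nodes")

    table = compute_centralities(gin)
    if metric not in table.columns:
        raise ValueError(f"unknown metric {metric!r}")
    values = table[metric]
    observed = values.loc[seeds].to_numpy()

    rng = np.random.default_rng(seed)
    all_vals = values.to_numpy()
    n = len(all_vals)
    k = len(seeds)
    null = np.empty(n_boot * k)
    for b in range(n_boot):
        idx = rng.choice(n, size=k, replace=False)
        null[b * k:(b + 1) * k] = all_vals[idx]

    res = stats.mannwhitneyu(observed, null, alternative="two-sided")
    return BootstrapResult(
        metric=metric,
        observed=observed,
        null=null,
        u=float(res.statistic),
        p=float(res.pvalue),
        n_boot=n_boot,
    )
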