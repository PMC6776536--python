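"""Centrality tables, cluster-count optimization and bottleneck genes.

Betweenness (pair-normalized Brandes), closeness (Wasserman-Faust
component-scaled) and eigenvector centrality (power iteration on |A| of the
largest component) are computed per gene.  Genes are then clustered in
standardized (BC, CC, EC) space: the number of clusters is scanned with
silhouette and Calinski-Harabasz scores for both k-means and Ward
agglomerative clustering, a fixed k (4 by default) assigns the
alpha/beta/gamma/delta labels ordered by ascending mean betweenness
(delta = the bottleneck cluster), and the top-n genes per centrality are
extracted.

Shortest paths are on hops by default: augmented-GIN edge weights are
interaction scores, not distances.  A weighted mode (1/|w| edge lengths) is
available for completeness.
"""

from __future__ import annotations

import warnings

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from sklearn.preprocessing import StandardScaler

__all__ = [
    "compute_centralities",
    "optimize_cluster_count",
    "assign_centrality_clusters",
    "top_bottleneck_genes",
    "CLUSTER_LABELS",
]

CLUSTER_LABELS = ("alpha", "beta", "gamma", "delta")
_EC_TOL = 1e-12
_EC_MAXITER = 100_000


def _to_igraph(gin: nx.Graph):
    nodes = list(gin.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    edges = [(idx[u], idx[v]) for u, v in gin.edges]
    weights = [abs(d.get("weight", 1.0)) for _, _, d in gin.edges(data=True)]
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    return g, nodes, weights


def _largest_component(gin: nx.Graph) -> set:
    """Largest connected component; ties broken by the component containing
    the smallest node label (string order)."""
    comps = list(nx.connected_components(gin))
    if not comps:
        return set()
    return sorted(comps, key=lambda c: (-len(c), min(map(str, c))))[0]


def _eigenvector(gin: nx.Graph) -> dict:
    """Leading eigenvector of |A| on the largest component, L2 norm 1,
    non-negative entries; zero elsewhere.

    Power iteration on |A| + I (the shift guarantees convergence on
    bipartite components) to tolerance 1e-12.
    """
    out = {n: 0.0 for n in gin.nodes}
    comp = sorted(_largest_component(gin))
    if not comp:
        return out
    if len(comp) == 1:
        out[comp[0]] = 1.0
        return out
    idx = {n: i for i, n in enumerate(comp)}
    rows, cols, vals = [], [], []
    for u, v, d in gin.subgraph(comp).edges(data=True):
        w = abs(d.get("weight", 1.0))
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
        vals += [w, w]
    a = csr_matrix((vals, (rows, cols)), shape=(len(comp), len(comp)))
    x = np.full(len(comp), 1.0 / np.sqrt(len(comp)))
    for _ in range(_EC_MAXITER):
        y = a @ x + x  # (A + I) x
        y /= np.linalg.norm(y)
        if np.linalg.norm(y - x) < _EC_TOL:
            x = y
            break
        x = y
    x = np.abs(x)
    x /= np.linalg.norm(x)
    for n, i in idx.items():
        out[n] = float(x[i])
    return out


def compute_centralities(gin: nx.Graph, weighted: bool = False) -> pd.DataFrame:
    """Per-gene BC, CC and EC, indexed by gene.

    BC is normalized by the number of node pairs excluding the endpoint,
    (n-1)(n-2)/2; CC uses the Wasserman-Faust component scaling
    ((n_r-1)/(n-1)) * ((n_r-1)/sum d); EC is the unit-norm leading
    eigenvector of |A| on the largest component.  With ``weighted``,
    shortest-path lengths use 1/|w| edge distances instead of hops.
    """
    if gin.number_of_nodes() == 0:
        raise ValueError("empty network")
    g, nodes, absw = _to_igraph(gin)
    n = len(nodes)
    w = [1.0 / x if x > 0 else np.inf for x in absw] if weighted else None

    bc_raw = np.asarray(g.betweenness(weights=w, directed=False), dtype=float)
    denom = (n - 1) * (n - 2) / 2.0
    bc = bc_raw / denom if denom > 0 else np.zeros(n)

    dist = np.asarray(g.distances(weights=w), dtype=float)
    cc = np.zeros(n)
    for i in range(n):
        d = dist[i]
        reach = np.isfinite(d) & (np.arange(n) != i)
        n_r = int(reach.sum())
        tot = float(d[reach].sum())
        if n_r > 0 and tot > 0 and n > 1:
            cc[i] = (n_r / (n - 1)) * (n_r / tot)

    ec = _eigenvector(gin)
    return pd.DataFrame(
        {"BC": bc, "CC": cc, "EC": [ec[x] for x in nodes]},
        index=pd.Index(nodes, name="gene"),
    )


def _standardize(table: pd.DataFrame) -> np.ndarray:
    feats = table[["BC", "CC", "EC"]].to_numpy(dtype=float)
    if np.allclose(feats.std(axis=0), 0.0):
        raise ValueError("degenerate centrality table: all points identical")
    scaler = StandardScaler()
    x = scaler.fit_transform(feats)
    # constant features carry no information; standardize to exact zeros
    x[:, feats.std(axis=0) == 0] = 0.0
    return x


def optimize_cluster_count(
    table: pd.DataFrame,
    k_range=range(2, 11),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Scan cluster counts with silhouette and Calinski-Harabasz scores.

    Both k-means and Ward agglomerative clusterings are fitted on
    standardized (BC, CC, EC) features for every k in ``k_range`` (default
    2..10).  Returns (scan table, {method: optimal k}); the optimum is the
    silhouette argmax with ties to the smaller k.
    """
    k_range = list(k_range)
    if len(table) < max(k_range) + 1:
        raise ValueError("need more genes than the largest k scanned")
    x = _standardize(table)
    rows = []
    for k in k_range:
        for method in ("kmeans", "agglomerative"):
            if method == "kmeans":
                labels = KMeans(
                    n_clusters=k, n_init=50, random_state=seed
                ).fit_predict(x)
            else:
                labels = AgglomerativeClustering(
                    n_clusters=k, linkage="ward"
                ).fit_predict(x)
            if len(set(labels)) < 2:
                si, ch = np.nan, np.nan
            else:
                si = silhouette_score(x, labels)
                ch = calinski_harabasz_score(x, labels)
            rows.append({"k": k, "method": method, "SI": si, "CH": ch})
    scan = pd.DataFrame(rows)
    optimal = {}
    for method in ("kmeans", "agglomerative"):
        sub = scan[scan["method"] == method].dropna(subset=["SI"])
        best = sub.sort_values(["SI", "k"], ascending=[False, True]).iloc[0]
        optimal[method] = int(best["k"])
    return scan, optimal


def assign_centrality_clusters(
    table: pd.DataFrame, k: int = 4, seed: int = 0
) -> pd.DataFrame:
    """K-means cluster genes in centrality space, labeled by mean BC.

    Clusters are relabeled alpha..delta (for k = 4) by ascending mean
    betweenness, so the last label always marks the bottleneck-rich cluster.
    Returns a copy of the table with a ``cluster`` column.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(table) < k:
        raise ValueError("fewer genes than clusters")
    x = _standardize(table)
    raw = KMeans(n_clusters=k, n_init=50, random_state=seed).fit_predict(x)
    mean_bc = {
        c: float(table["BC"].to_numpy()[raw == c].mean()) for c in range(k)
    }
    order = sorted(range(k), key=lambda c: (mean_bc[c], c))
    if k <= len(CLUSTER_LABELS):
        names = list(CLUSTER_LABELS[:k])
    else:
        names = [f"c{i}" for i in range(k)]
    relabel = {c: names[i] for i, c in enumerate(order)}
    out = table.copy()
    out["cluster"] = [relabel[c] for c in raw]
    return out


def top_bottleneck_genes(
    table: pd.DataFrame, metric: str = "BC", n: int = 5
) -> pd.DataFrame:
    """Top-n genes by a centrality metric; ties broken by gene name."""
    if metric not in table.columns:
        raise ValueError(f"unknown metric {metric!r}")
    if len(table) == 0:
        raise ValueError("empty centrality table")
    if n > len(table):
        warnings.warn(f"requested top {n} of {len(table)} genes; returning all")
        n = len(table)
    ranked = table.copy()
    ranked["_name"] = ranked.index.astype(str)
    ranked = ranked.sort_values(
        by=[metric, "_name"], ascending=[False, True], kind="mergesort"
    ).drop(columns="_name")
    return ranked.head(n)[[metric]]
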