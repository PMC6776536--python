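"""Clustering of interaction profiles across the (background x probe) grid.

Profiles are stacked into a matrix (rows = screens, columns = genes) of
min-max normalized Z-scores; genes unscored in a profile are masked and
imputed with the column median for distance computations.  Agglomerative
clustering over rows yields a dendrogram cut into a configurable number of
clades (3 by default); focused panels re-normalize a column subset and
cluster both genes and profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .scoring import InteractionProfile

__all__ = [
    "ProfileMatrix",
    "build_profile_matrix",
    "hierarchical_cluster",
    "focused_subcluster",
    "linkage_to_newick",
]


@dataclass
class ProfileMatrix:
    """Min-max normalized Z-score matrix with a missingness mask.

    ``values``: rows = profile labels ('background:probe'), columns = genes,
    entries in [0, 1] per column (constant columns are all 0).  ``mask`` is
    True where the source profile scored the gene.
    """

    values: pd.DataFrame
    mask: pd.DataFrame

    def imputed(self) -> pd.DataFrame:
        """Masked entries replaced by the column median of observed values
        (columns with no observation at all fall back to 0)."""
        vals = self.values.where(self.mask)
        med = vals.median(axis=0)
        out = vals.fillna(med).fillna(0.0)
        return out


def _minmax(frame: pd.DataFrame, mask: pd.DataFrame) -> pd.DataFrame:
    vals = frame.where(mask)
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    span = hi - lo
    out = (vals - lo).div(span.replace(0.0, np.nan))
    out = out.fillna(0.0)  # constant or unobserved columns -> 0
    return out


def build_profile_matrix(
    profiles: list[InteractionProfile],
    gene_universe: list[str] | None = None,
) -> ProfileMatrix:
    """Stack profiles into a per-gene min-max normalized Z matrix.

    A gene is 'observed' in a profile when it was scored and not excluded;
    linkage-excluded and missing genes are masked.  Normalization is per
    column (gene) across the profile rows.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    if gene_universe is None:
        universe: set[str] = set()
        for p in profiles:
            universe |= set(p.table.index)
        gene_universe = sorted(universe)
    if not gene_universe:
        raise ValueError("empty gene universe")

    labels = [f"{p.background}:{p.probe}" for p in profiles]
    z = pd.DataFrame(np.nan, index=labels, columns=gene_universe)
    mask = pd.DataFrame(False, index=labels, columns=gene_universe)
    for lab, p in zip(labels, profiles):
        t = p.table
        ok = t.index[(t["excluded_reason"] == "none") & np.isfinite(t["z"])]
        ok = [g for g in ok if g in z.columns]
        z.loc[lab, ok] = t.loc[ok, "z"].astype(float).to_numpy()
        mask.loc[lab, ok] = True
    values = _minmax(z, mask)
    return ProfileMatrix(values=values, mask=mask)


def hierarchical_cluster(
    matrix: ProfileMatrix,
    linkage: str = "average",
    distance: str = "euclidean",
    n_clades: int = 3,
) -> dict:
    """Agglomerative tree over profile rows, cut into flat clades.

    Returns a dict with the scipy linkage matrix ('linkage'), leaf labels,
    flat clade ids ('clades', 1-based as from fcluster), cophenetic
    distances, and a Newick rendering of the dendrogram.
    """
    data = matrix.imputed()
    if len(data) < 3:
        raise ValueError("need at least three profiles for clade extraction")
    if data.isna().any().any():
        raise ValueError("NaN left after imputation")
    x = data.to_numpy(dtype=float)
    metric = "correlation" if distance == "correlation" else "euclidean"
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires euclidean distances")
    d = pdist(x, metric=metric)
    d = np.nan_to_num(d, nan=0.0)  # correlation of constant rows
    z = hierarchy.linkage(d, method=linkage)
    clades = hierarchy.fcluster(z, t=n_clades, criterion="maxclust")
    coph = hierarchy.cophenet(z)
    labels = list(data.index)
    return {
        "linkage": z,
        "labels": labels,
        "clades": pd.Series(clades, index=labels, name="clade"),
        "cophenetic": coph,
        "newick": linkage_to_newick(z, labels),
    }


def focused_subcluster(
    matrix: ProfileMatrix,
    gene_panel: list[str],
    linkage: str = "average",
    distance: str = "euclidean",
    n_clades: int | None = None,
) -> dict:
    """Re-normalize a gene-panel column subset and cluster both ways.

    Panel genes absent from the matrix are dropped with a warning; the
    remaining columns are min-max re-normalized before clustering profiles
    (rows) and genes (columns).  Returns {'matrix', 'rows', 'genes'} where
    rows/genes are hierarchical_cluster-style dicts.
    """
    present = [g for g in gene_panel if g in matrix.values.columns]
    missing = [g for g in gene_panel if g not in matrix.values.columns]
    if missing:
        warnings.warn(f"{len(missing)} panel gene(s) not in matrix; dropped")
    if not present:
        raise ValueError("no panel gene present in the matrix")
    sub = ProfileMatrix(
        values=_minmax(matrix.values[present], matrix.mask[present]),
        mask=matrix.mask[present],
    )
    if n_clades is None:
        n_clades = min(3, len(sub.values) - 1) or 1
    rows = hierarchical_cluster(sub, linkage, distance, n_clades=n_clades)
    transposed = ProfileMatrix(values=sub.imputed().T, mask=sub.mask.T)
    if len(present) >= 3:
        genes = hierarchical_cluster(
            ProfileMatrix(values=_minmax(transposed.values, transposed.mask),
                          mask=transposed.mask),
            linkage, distance, n_clades=min(3, len(present) - 1),
        )
    else:
        genes = None
    return {"matrix": sub, "rows": rows, "genes": genes}


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(z)

    def recurse(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            name = labels[node.id].replace(" ", "_").replace(",", "_")
            return f"{name}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"
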