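"""Interaction scoring: colony sizes -> growth ratios -> Z-scores -> called hits.

A screen compares a treated plate set against its paired control (drug vs
vehicle, or double-mutant vs single-mutant array).  Per-gene growth ratios are
converted to Z-scores so that growth *defects* score positive, one-sided normal
p-values are attached, and hits are called at configurable thresholds
(Z > 2.0 and P < 0.05 by default).  Genes in the meiotic linkage window of an
SGA query locus can be excluded, and hit sets from several genetic backgrounds
can be intersected/differenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateDistributionError,
    DegeneratePlateError,
    LayoutError,
)

__all__ = [
    "Position",
    "ColonyPlate",
    "ScoringConfig",
    "InteractionProfile",
    "normalize_plate",
    "compute_ratios",
    "score_profile",
    "exclude_linkage",
    "hit_set_algebra",
]


class Position(NamedTuple):
    """A colony position: (plate, row, col), all 0-based except plate id."""

    plate: int
    row: int
    col: int


@dataclass
class ColonyPlate:
    """One plate of colony sizes.

    ``grid`` maps positions to colony areas (>= 0); ``genes`` maps the same
    positions to gene ids (``None`` for empty spots); ``border_flags`` marks
    the outermost row/column, which show a systematic growth advantage on
    pinned arrays and are excluded from normalization statistics.
    """

    plate_id: int
    condition: str
    background: str
    grid: dict[Position, float]
    genes: dict[Position, str | None]
    border_flags: dict[Position, bool]

    def positions(self) -> list[Position]:
        return list(self.grid)

    def non_empty(self) -> list[Position]:
        return [p for p, g in self.genes.items() if g is not None]


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds and options for hit calling.

    z_threshold/p_threshold: joint hit criteria (defaults Z > 2.0, P < 0.05).
    linkage_window_bp: half-width of the query linkage-exclusion window.
    use_log_ratio: score log2 ratios (symmetrizes multiplicative noise).
    robust_center: median/1.4826*MAD instead of mean/SD.
    exclude_border: if True, border genes are never called hits.
    """

    z_threshold: float = 2.0
    p_threshold: float = 0.05
    linkage_window_bp: int = 25_000
    use_log_ratio: bool = True
    robust_center: bool = False
    exclude_border: bool = False

    def __post_init__(self):
        if self.z_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class InteractionProfile:
    """Per-gene scores for one (background x probe) screen.

    ``table`` is indexed by gene with columns ratio, z, p, hit,
    excluded_reason ('none', 'linkage', 'border' or 'missing') and border.
    """

    background: str
    probe: str
    table: pd.DataFrame
    config: ScoringConfig = field(default_factory=ScoringConfig)

    @property
    def hits(self) -> set[str]:
        return set(self.table.index[self.table["hit"]])

    def to_tsv(self, path) -> None:
        out = self.table.reset_index().rename(columns={"index": "gene"})
        out.to_csv(path, sep="\t", index=False)


def normalize_plate(plate: ColonyPlate) -> ColonyPlate:
    """Divide sizes by the median of non-border, non-empty colonies.

    After normalization the median non-border colony has size 1, which makes
    plates (and the global treatment inhibition they carry) comparable.
    """
    occupied = plate.non_empty()
    if len(occupied) < 0.5 * len(plate.grid):
        raise DegeneratePlateError(
            f"plate {plate.plate_id}: fewer than 50% of positions occupied"
        )
    interior = [
        plate.grid[p]
        for p in occupied
        if not plate.border_flags.get(p, False) and plate.grid[p] > 0
    ]
    if not interior:
        raise DegeneratePlateError(
            f"plate {plate.plate_id}: no usable interior colonies"
        )
    med = float(np.median(interior))
    if med <= 0:
        raise DegeneratePlateError(f"plate {plate.plate_id}: zero median size")
    grid = {p: s / med for p, s in plate.grid.items()}
    return replace(plate, grid=grid)


def _gene_map_key(plates: Sequence[ColonyPlate]) -> dict[Position, str]:
    out: dict[Position, str] = {}
    for pl in plates:
        for pos, g in pl.genes.items():
            if g is not None:
                out[pos] = g
    return out


def compute_ratios(
    treated: Sequence[ColonyPlate] | ColonyPlate,
    control: Sequence[ColonyPlate] | ColonyPlate,
) -> pd.DataFrame:
    """Per-gene treated/control size ratios from normalized plate pairs.

    Replicate positions of the same gene are collapsed by median before the
    ratio is taken.  Returns a DataFrame indexed by gene with columns
    ``ratio`` (NaN when the control is zero), ``border`` (True when every
    position of the gene is a border position) and ``missing``.
    """
    if isinstance(treated, ColonyPlate):
        treated = [treated]
    if isinstance(control, ColonyPlate):
        control = [control]
    tmap, cmap = _gene_map_key(treated), _gene_map_key(control)
    if tmap != cmap:
        raise LayoutError("treated and control plates have different gene maps")

    def collapse(plates: Sequence[ColonyPlate]):
        sizes: dict[str, list[float]] = {}
        border: dict[str, list[bool]] = {}
        for pl in plates:
            for pos, g in pl.genes.items():
                if g is None:
                    continue
                sizes.setdefault(g, []).append(pl.grid[pos])
                border.setdefault(g, []).append(pl.border_flags.get(pos, False))
        med = {g: float(np.median(v)) for g, v in sizes.items()}
        brd = {g: all(v) for g, v in border.items()}
        return med, brd

    tmed, tbrd = collapse(treated)
    cmed, _ = collapse(control)
    genes = sorted(tmed)
    ratio = np.full(len(genes), np.nan)
    for i, g in enumerate(genes):
        if cmed[g] > 0:
            ratio[i] = tmed[g] / cmed[g]
    df = pd.DataFrame(
        {
            "ratio": ratio,
            "border": [tbrd[g] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    df["missing"] = ~np.isfinite(df["ratio"])
    return df


def score_profile(
    ratios: pd.DataFrame | Mapping[str, float],
    config: ScoringConfig | None = None,
    background: str = "",
    probe: str = "",
    min_scorable: int = 20,
) -> InteractionProfile:
    """Z-score growth ratios and call hits.

    The score is z(g) = (center - x(g)) / spread with x = log2(ratio) when
    ``use_log_ratio``; the sign convention makes growth defects positive, so
    a hypersensitive deletion (small ratio) has a large positive Z.  p is the
    one-sided upper normal tail of z.  Center/spread are estimated from
    non-border, non-missing genes (mean/SD, or median/1.4826*MAD when
    ``robust_center``).
    """
    config = config or ScoringConfig()
    if not isinstance(ratios, pd.DataFrame):
        ratios = pd.DataFrame(
            {"ratio": pd.Series(dict(ratios), dtype=float)}
        ).rename_axis("gene")
        ratios["border"] = False
        ratios["missing"] = ~np.isfinite(ratios["ratio"])

    scorable = (~ratios["missing"]) & (ratios["ratio"] > 0)
    if int(scorable.sum()) < min_scorable:
        raise ValueError(
            f"need at least {min_scorable} scorable genes to estimate spread"
        )

    x = pd.Series(np.nan, index=ratios.index)
    vals = ratios.loc[scorable, "ratio"].astype(float)
    x.loc[scorable] = np.log2(vals) if config.use_log_ratio else vals

    est = x[scorable & ~ratios["border"]]
    if len(est) < min(min_scorable, 20):  # all-border: fall back to every scorable gene
        est = x[scorable]
    if config.robust_center:
        center = float(est.median())
        spread = 1.4826 * float((est - center).abs().median())
    else:
        center = float(est.mean())
        spread = float(est.std(ddof=1))
    if not np.isfinite(spread) or spread <= 0:
        raise DegenerateDistributionError("zero spread: ratios are constant")

    z = (center - x) / spread
    p = pd.Series(stats.norm.sf(z.to_numpy()), index=z.index)

    reason = pd.Series("none", index=ratios.index, dtype=object)
    reason[ratios["missing"]] = "missing"
    if config.exclude_border:
        reason[ratios["border"] & (reason == "none")] = "border"
    hit = (
        (z > config.z_threshold)
        & (p < config.p_threshold)
        & (reason == "none")
    ).fillna(False)

    table = pd.DataFrame(
        {
            "ratio": ratios["ratio"],
            "z": z,
            "p": p,
            "hit": hit.astype(bool),
            "excluded_reason": reason,
            "border": ratios["border"].astype(bool),
        }
    )
    return InteractionProfile(background, probe, table, config)


def exclude_linkage(
    profile: InteractionProfile,
    query_gene: str,
    library,
    window_bp: int | None = None,
) -> InteractionProfile:
    """Mark genes within +/- window_bp of the query locus as linkage-excluded.

    Double mutants of genes meiotically linked to the SGA query are
    under-recovered for reasons unrelated to epistasis, so they are removed
    from the hit list.  Distance is measured between gene start coordinates on
    the query chromosome; window 0 excludes only the query locus itself.
    """
    if query_gene not in library.linkage:
        raise KeyError(f"query gene {query_gene!r} has no linkage coordinates")
    if window_bp is None:
        window_bp = profile.config.linkage_window_bp
    q_chrom, q_start, _ = library.linkage[query_gene]

    table = profile.table.copy()
    for gene in table.index:
        rec = library.linkage.get(gene)
        if rec is None:
            continue
        chrom, start, _ = rec
        if chrom == q_chrom and abs(start - q_start) <= window_bp:
            table.loc[gene, "excluded_reason"] = "linkage"
    table["hit"] = (
        (table["z"] > profile.config.z_threshold)
        & (table["p"] < profile.config.p_threshold)
        & (table["excluded_reason"] == "none")
    ).fillna(False).astype(bool)
    return InteractionProfile(profile.background, profile.probe, table, profile.config)


def hit_set_algebra(profiles: Iterable[InteractionProfile]) -> dict:
    """Common/unique hit-set report across backgrounds for one probe.

    Partitions the union of hits by the exact set of backgrounds each gene is
    hit in, and derives 'common to all' and 'unique per background' views.
    The exact-pattern classes are disjoint and their sizes sum to the union.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    probes = {p.probe for p in profiles}
    if len(probes) != 1:
        raise ValueError(f"profiles mix probes: {sorted(probes)}")
    backgrounds = [p.background for p in profiles]
    if len(set(backgrounds)) != len(backgrounds):
        raise ValueError("duplicate backgrounds")

    hits = {p.background: p.hits for p in profiles}
    union = set().union(*hits.values())
    patterns: dict[frozenset, set[str]] = {}
    for g in union:
        key = frozenset(b for b in backgrounds if g in hits[b])
        patterns.setdefault(key, set()).add(g)

    all_bg = frozenset(backgrounds)
    common_all = patterns.get(all_bg, set())
    unique = {
        b: patterns.get(frozenset([b]), set()) for b in backgrounds
    }
    return {
        "probe": profiles[0].probe,
        "backgrounds": backgrounds,
        "hits": hits,
        "union": union,
        "union_size": len(union),
        "common_all": common_all,
        "exact_patterns": {tuple(sorted(k)): v for k, v in patterns.items()},
        "unique": unique,
    }
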