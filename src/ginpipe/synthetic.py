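"""Synthetic screens, networks and ontologies with known ground truth.

The generator emulates the ingredients of an arrayed chemical-genetic /
SGA study: a deletion library pinned in 384 or 1536 format with border
positions flagged, colony sizes with multiplicative lognormal noise, a
global drug-level growth inhibition (~40% by default) with planted
hypersensitive deletions, a planted-partition (stochastic block model)
weighted global genetic-interaction network, and a small rooted GO DAG with
sparse, optionally module-biased annotations.  Every generator is
deterministic for a fixed seed, so downstream stages can be tested against
the planted truth without any external data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .enrichment import GODag
from .exceptions import CapacityError
from .scoring import ColonyPlate, Position

__all__ = [
    "DeletionLibrary",
    "SyntheticTruth",
    "generate_library",
    "generate_screen_pair",
    "generate_global_gin",
    "generate_go",
    "study_truth",
    "DEFAULT_BACKGROUNDS",
    "DEFAULT_PROBES",
]

GRIDS = {384: (16, 24), 1536: (32, 48)}
N_CHROMOSOMES = 16
GENE_SPACING_BP = 12_000
GENE_LENGTH_BP = 1_000
BASELINE_SIZE = 500.0  # median colony area, size units
BORDER_ADVANTAGE = 1.25  # edge colonies grow larger (more nutrient access)

DEFAULT_BACKGROUNDS = ("S288C", "UWOPS87-2421", "Y55", "YPS606")
#: probe -> kind; drugs probe via treatment, queries via double mutants
DEFAULT_PROBES = {
    "atorvastatin": "drug",
    "cerivastatin": "drug",
    "hmg1": "query",
    "hmg2": "query",
    "arv1": "query",
}

#: per-probe planted hit-set design: (union across 4 backgrounds, common to
#: all 4, shared by exactly one background pair, shared by all-but-the-first
#: background).  The last class emulates hits common to the non-reference
#: (resistant) strains only.  Screen totals sum to
#: union + 3*common + pairwise + 2*resistant_only = 1660 overall.
DEFAULT_HIT_DESIGN = {
    "atorvastatin": (288, 4, 19, 1),
    "cerivastatin": (283, 3, 21, 0),
    "hmg1": (339, 0, 21, 0),
    "hmg2": (181, 1, 21, 0),
    "arv1": (425, 5, 21, 0),
}


@dataclass
class DeletionLibrary:
    """An arrayed deletion collection with plate layout and gene linkage.

    ``positions`` maps every plate position to a gene (or None when empty);
    ``linkage`` maps each gene to (chromosome, start_bp, end_bp) on one of 16
    synthetic chromosomes with uniform 12-kb gene spacing.
    """

    genes: list[str]
    positions: dict[Position, str | None]
    linkage: dict[str, tuple[str, int, int]]
    density: int

    @property
    def grid(self) -> tuple[int, int]:
        return GRIDS[self.density]

    @property
    def n_plates(self) -> int:
        return 1 + max(p.plate for p in self.positions)

    def is_border(self, pos: Position) -> bool:
        rows, cols = self.grid
        return pos.row in (0, rows - 1) or pos.col in (0, cols - 1)

    def gene_positions(self) -> dict[str, list[Position]]:
        out: dict[str, list[Position]] = {}
        for pos, g in self.positions.items():
            if g is not None:
                out.setdefault(g, []).append(pos)
        return out


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic study.

    planted_hits: (background, probe) -> hypersensitive gene set.
    effect_size: extra fractional growth reduction of a planted hit (0-1).
    planted_partition: gene -> block id of the global network (may be empty
    until the global network is generated).
    noise_cv: coefficient of variation of colony-size noise.
    query_genes: probe -> query locus for SGA-style probes.
    """

    planted_hits: dict[tuple[str, str], set[str]]
    effect_size: float = 0.5
    planted_partition: dict[str, int] = field(default_factory=dict)
    noise_cv: float = 0.10
    query_genes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.effect_size < 1.0):
            raise ValueError("effect_size must lie in (0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def generate_library(
    n_genes: int, density: int = 1536, seed: int = 0,
    n_plates: int | None = None,
) -> DeletionLibrary:
    """Lay out ``n_genes`` deletions on 384- or 1536-density plates.

    Plates are added as needed (``ceil(n_genes/density)``); gene placement is
    shuffled under the seed so genes mix between border and interior.  Linkage
    assigns contiguous blocks of genes to 16 chromosomes at 12-kb spacing,
    which makes linkage-window exclusion exercisable.
    """
    if density not in GRIDS:
        raise ValueError(f"density must be one of {sorted(GRIDS)}")
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    needed = math.ceil(n_genes / density)
    if n_plates is None:
        n_plates = needed
    elif n_plates * density < n_genes:
        raise CapacityError(
            f"{n_genes} genes exceed {n_plates} plates x {density} positions"
        )
    rows, cols = GRIDS[density]
    all_pos = [
        Position(p, r, c)
        for p in range(n_plates)
        for r in range(rows)
        for c in range(cols)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(all_pos))
    genes = [gene_name(i) for i in range(n_genes)]
    positions: dict[Position, str | None] = {p: None for p in all_pos}
    for gi, oi in enumerate(order[:n_genes]):
        positions[all_pos[oi]] = genes[gi]

    per_chrom = math.ceil(n_genes / N_CHROMOSOMES)
    linkage = {}
    for i, g in enumerate(genes):
        chrom = f"chr{i // per_chrom + 1:02d}"
        start = (i % per_chrom) * GENE_SPACING_BP
        linkage[g] = (chrom, start, start + GENE_LENGTH_BP)
    return DeletionLibrary(genes, positions, linkage, density)


def generate_screen_pair(
    library: DeletionLibrary,
    truth: SyntheticTruth,
    background: str,
    probe: str,
    inhibition: float = 0.4,
    seed: int = 0,
) -> tuple[list[ColonyPlate], list[ColonyPlate]]:
    """Simulate one (control, treated) plate pair set for a screen.

    Control colonies are lognormal around a median of 500 size units with
    CV = truth.noise_cv; border positions get a fixed growth advantage on
    both plates (it cancels in ratios but perturbs naive plate medians).
    Treated colonies scale the control median by (1 - inhibition) globally
    and by (1 - effect_size) additionally for planted hits, with an
    independent noise draw.  Returns (control_plates, treated_plates).
    """
    if not (0.0 <= inhibition < 1.0):
        raise ValueError("inhibition must lie in [0, 1)")
    key = (background, probe)
    if key not in truth.planted_hits:
        raise KeyError(f"no planted truth for background/probe {key}")
    hits = truth.planted_hits[key]
    sigma = math.sqrt(math.log(1.0 + truth.noise_cv**2))
    rng = np.random.default_rng(seed)

    rows, cols = library.grid

    def make_plates(condition: str, treated: bool) -> list[ColonyPlate]:
        plates = []
        for plate_id in range(library.n_plates):
            grid: dict[Position, float] = {}
            genes: dict[Position, str | None] = {}
            border: dict[Position, bool] = {}
            for r in range(rows):
                for c in range(cols):
                    pos = Position(plate_id, r, c)
                    g = library.positions.get(pos)
                    genes[pos] = g
                    border[pos] = library.is_border(pos)
                    if g is None:
                        grid[pos] = 0.0
                        continue
                    mu = BASELINE_SIZE
                    if treated:
                        mu *= 1.0 - inhibition
                        if g in hits:
                            mu *= 1.0 - truth.effect_size
                    if border[pos]:
                        mu *= BORDER_ADVANTAGE
                    noise = math.exp(sigma * rng.standard_normal()) if sigma else 1.0
                    grid[pos] = mu * noise
            plates.append(
                ColonyPlate(plate_id, condition, background, grid, genes, border)
            )
        return plates

    control = make_plates("vehicle", treated=False)
    treated = make_plates(f"{probe}", treated=True)
    return control, treated


def generate_global_gin(
    n_genes: int = 2000,
    n_blocks: int = 10,
    p_in: float = 0.06,
    p_out: float = 0.002,
    weight_law=None,
    seed: int = 0,
    genes: list[str] | None = None,
) -> tuple[nx.Graph, dict[str, int]]:
    """Planted-partition weighted global GIN.

    Genes are assigned round-robin to ``n_blocks`` blocks; edges appear with
    probability p_in within a block and p_out between blocks (no self-loops).
    Default edge weights are |N(0.25, 0.1)| with 10% of signs flipped
    (interaction scores straddling the 0.12 stringent cutoff) and edge
    p-values ~ Beta(0.5, 10).  Returns (graph, gene -> block id).
    """
    if not (0.0 <= p_out <= 1.0 and 0.0 <= p_in <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if p_in <= p_out:
        raise ValueError("p_in must exceed p_out")
    if n_blocks < 2:
        raise ValueError("need at least two blocks")
    if genes is None:
        genes = [gene_name(i) for i in range(n_genes)]
    elif len(genes) != n_genes:
        raise ValueError("genes list length must equal n_genes")
    rng = np.random.default_rng(seed)
    block = np.arange(n_genes) % n_blocks
    iu, ju = np.triu_indices(n_genes, k=1)
    prob = np.where(block[iu] == block[ju], p_in, p_out)
    keep = rng.random(len(prob)) < prob
    ei, ej = iu[keep], ju[keep]
    m = len(ei)
    if weight_law is None:
        w = np.abs(rng.normal(0.25, 0.1, size=m))
        w[rng.random(m) < 0.10] *= -1.0
    else:
        w = np.asarray(weight_law(rng, m), dtype=float)
    p_edge = rng.beta(0.5, 10.0, size=m)

    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edges_from(
        (genes[a], genes[b], {"weight": float(wi), "p": float(pi)})
        for a, b, wi, pi in zip(ei, ej, w, p_edge)
    )
    partition = {genes[i]: int(block[i]) for i in range(n_genes)}
    return g, partition


def generate_go(
    genes: list[str],
    n_terms: int = 120,
    depth: int = 4,
    annotation_rate: float = 0.01,
    seed: int = 0,
    partition: dict[str, int] | None = None,
    bias: float = 0.0,
) -> tuple[GODag, dict[str, set[str]]]:
    """A small rooted GO-like DAG plus true-path-propagated annotations.

    Terms sit on levels 1..depth under a single root; every non-root term has
    1-2 parents on the level above.  Leaf terms annotate genes at
    ``annotation_rate``; with probability ``bias`` an annotated gene is drawn
    from one focal block of ``partition`` (planting function-module
    correlation).  Direct annotations are propagated to every ancestor.
    """
    if depth < 2:
        raise ValueError("depth must be at least 2")
    if not (0.0 <= annotation_rate <= 1.0 and 0.0 <= bias <= 1.0):
        raise ValueError("annotation_rate and bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    root = "T0000"
    ns = "biological_process"
    terms = {root: ("root", ns)}
    parents: dict[str, set[str]] = {root: set()}
    levels: dict[int, list[str]] = {0: [root]}
    for i in range(1, n_terms + 1):
        t = f"T{i:04d}"
        level = i if i <= depth else int(rng.integers(1, depth + 1))
        terms[t] = (f"process {i}", ns)
        pool = levels[level - 1]
        k = 1 if len(pool) == 1 else int(rng.integers(1, 3))
        chosen = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        parents[t] = {pool[int(c)] for c in chosen}
        levels.setdefault(level, []).append(t)
    dag = GODag(terms, parents)

    has_child = {p for ps in parents.values() for p in ps}
    leaves = [t for t in terms if t not in has_child]
    blocks: dict[int, list[str]] = {}
    if partition:
        gene_set = set(genes)
        for g, b in partition.items():
            if g in gene_set:
                blocks.setdefault(b, []).append(g)

    direct: dict[str, set[str]] = {g: set() for g in genes}
    gene_arr = list(genes)
    for t in leaves:
        n_ann = rng.binomial(len(genes), annotation_rate)
        focal = None
        if blocks and bias > 0:
            focal = blocks[int(rng.choice(sorted(blocks)))]
        chosen: set[str] = set()
        while len(chosen) < n_ann:
            if focal and rng.random() < bias:
                chosen.add(focal[int(rng.integers(len(focal)))])
            else:
                chosen.add(gene_arr[int(rng.integers(len(gene_arr)))])
        for g in chosen:
            direct[g].add(t)

    annotations: dict[str, set[str]] = {}
    for g, ts in direct.items():
        if not ts:
            continue
        full: set[str] = set()
        for t in ts:
            full |= dag.ancestors(t)
        annotations[g] = full
    dag.set_corpus(annotations)
    return dag, annotations


def _pick_query_genes(library: DeletionLibrary, probes, rng) -> dict[str, str]:
    queries = [p for p, kind in probes.items() if kind == "query"]
    chosen = rng.choice(len(library.genes), size=len(queries), replace=False)
    return {q: library.genes[int(c)] for q, c in zip(queries, chosen)}


def study_truth(
    library: DeletionLibrary,
    seed: int = 0,
    effect_size: float = 0.5,
    noise_cv: float = 0.10,
    backgrounds=DEFAULT_BACKGROUNDS,
    probes: dict[str, str] | None = None,
    hit_design: dict[str, tuple[int, int, int]] | None = None,
    linkage_window_bp: int = 25_000,
) -> SyntheticTruth:
    """Plant the full study's hit-set structure as ground truth.

    For each probe, a union of hypersensitive genes is split into a core
    common to every background, genes shared by exactly one background pair,
    and background-unique genes (the default design reproduces the study-scale
    tallies: unions 288/283/339/181/425, cores 4/3/0/1/5, 1660 screen hits in
    total).  Hits for SGA-style query probes avoid the query's linkage window
    so that linkage exclusion does not consume planted signal.
    """
    probes = dict(probes or DEFAULT_PROBES)
    hit_design = dict(hit_design or DEFAULT_HIT_DESIGN)
    rng = np.random.default_rng(seed)
    query_genes = _pick_query_genes(library, probes, rng)

    bgs = list(backgrounds)
    pairs = list(itertools.combinations(range(len(bgs)), 2))
    planted: dict[tuple[str, str], set[str]] = {
        (b, p): set() for b in bgs for p in probes
    }
    for probe in probes:
        design = hit_design[probe]
        if len(design) == 3:
            union_n, common_n, pair_n = design
            triple_n = 0
        else:
            union_n, common_n, pair_n, triple_n = design
        pool = list(library.genes)
        q = query_genes.get(probe)
        if q is not None:
            q_chrom, q_start, _ = library.linkage[q]
            pool = [
                g
                for g in pool
                if not (
                    library.linkage[g][0] == q_chrom
                    and abs(library.linkage[g][1] - q_start) <= linkage_window_bp
                )
            ]
        if union_n > len(pool):
            raise CapacityError(f"union for {probe} exceeds eligible genes")
        chosen = [pool[int(i)] for i in
                  rng.choice(len(pool), size=union_n, replace=False)]
        core = chosen[:common_n]
        paired = chosen[common_n:common_n + pair_n]
        tripled = chosen[common_n + pair_n:common_n + pair_n + triple_n]
        unique = chosen[common_n + pair_n + triple_n:]
        for g in core:
            for b in bgs:
                planted[(b, probe)].add(g)
        if not pairs:  # single-background design: shared classes degrade to unique
            unique = paired + tripled + unique
            paired, tripled = [], []
        for i, g in enumerate(paired):
            a, b = pairs[i % len(pairs)]
            planted[(bgs[a], probe)].add(g)
            planted[(bgs[b], probe)].add(g)
        for g in tripled:  # shared by every non-reference background
            for b in bgs[1:]:
                planted[(b, probe)].add(g)
        for i, g in enumerate(unique):
            planted[(bgs[i % len(bgs)], probe)].add(g)

    return SyntheticTruth(
        planted_hits=planted,
        effect_size=effect_size,
        noise_cv=noise_cv,
        query_genes=query_genes,
    )
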