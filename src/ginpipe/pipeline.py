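"""End-to-end orchestration of a probe x background interaction study.

A study is a grid of screens (genetic backgrounds x probes, where a probe is
a drug treatment or an SGA query gene).  For every cell the pipeline scores
the screen into an interaction profile; across cells it runs hit-set algebra
per probe and hierarchical profile clustering; per cell it assembles an
augmented GIN, partitions it into Louvain communities, computes centralities
with alpha-delta cluster labels and top bottleneck genes, validates seed
centrality against a bootstrap null, and runs GO enrichment (plus optional
SAFE neighborhood enrichment).  A manifest records seeds, parameters and
SHA-256 hashes of every written artifact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import io as gio
from .centrality import (
    assign_centrality_clusters,
    compute_centralities,
    optimize_cluster_count,
    top_bottleneck_genes,
)
from .community import community_go_coverage, louvain_partition
from .enrichment import SafeConfig, hypergeom_enrich, safe_enrichment, uniqueness_table
from .network import bootstrap_centrality_test, build_augmented_gin
from .profiles import build_profile_matrix, hierarchical_cluster
from .scoring import (
    ScoringConfig,
    compute_ratios,
    exclude_linkage,
    hit_set_algebra,
    normalize_plate,
    score_profile,
)
from .synthetic import (
    DEFAULT_BACKGROUNDS,
    DEFAULT_PROBES,
    gene_name,
    generate_global_gin,
    generate_go,
    generate_library,
    generate_screen_pair,
    study_truth,
)

__all__ = ["StudyConfig", "StudyResult", "run_synthetic_study", "validate_inputs"]


@dataclass
class StudyConfig:
    """One source of truth for a synthetic study run."""

    backgrounds: tuple = DEFAULT_BACKGROUNDS
    probes: dict = field(default_factory=lambda: dict(DEFAULT_PROBES))
    seed: int = 0
    # screens
    n_genes: int = 1536
    density: int = 1536
    inhibition: float = 0.4
    effect_size: float = 0.5
    noise_cv: float = 0.10
    hit_design: dict | None = None  # per-probe planted design override
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    # global network
    global_n_genes: int = 2000
    n_blocks: int = 10
    p_in: float = 0.06
    p_out: float = 0.002
    # augmentation
    hop_bound: int = 2
    weight_cutoff: float = 0.12
    p_cutoff: float = 0.05
    # downstream
    louvain_resolution: float = 1.0
    n_clades: int = 3
    k_clusters: int = 4
    top_n: int = 5
    n_boot: int = 1000
    run_cluster_scan: bool = True
    # annotations
    go_terms: int = 120
    go_depth: int = 4
    go_rate: float = 0.01
    go_bias: float = 0.5
    # SAFE
    include_safe: bool = True
    safe_radius: float = 7.5
    safe_alpha: float = 0.05
    safe_median_edge_length: float = 4.0


@dataclass
class StudyResult:
    """Everything a study run produced, keyed by (background, probe)."""

    config: StudyConfig
    library: object
    truth: object
    global_gin: nx.Graph
    dag: object
    annotations: dict
    profiles: dict
    hit_reports: dict
    profile_clustering: dict | None
    gins: dict
    partitions: dict
    coverage: dict
    centrality: dict
    cluster_scans: dict
    top_genes: dict
    bootstrap: dict
    enrichment: dict
    safe: dict
    manifest: dict

    def community_counts(self) -> dict:
        return {k: p.n_communities for k, p in self.partitions.items()}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _cell_seed(base: int, i: int) -> int:
    return int((base * 1_000_003 + 7919 * (i + 1)) % (2**31 - 1))


def _layout(gin: nx.Graph, seed: int) -> dict:
    """Seeded force-directed 2D map of a network (igraph Fruchterman-
    Reingold from seeded random starting coordinates)."""
    import igraph as ig

    nodes = list(gin.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    g = ig.Graph(n=len(nodes),
                 edges=[(idx[u], idx[v]) for u, v in gin.edges],
                 directed=False)
    rng = np.random.default_rng(seed)
    start = rng.standard_normal((len(nodes), 2)).tolist()
    coords = g.layout_fruchterman_reingold(niter=100, seed=start).coords
    return {n: tuple(coords[idx[n]]) for n in nodes}


def run_synthetic_study(config: StudyConfig | None = None,
                        outdir: str | Path | None = None) -> StudyResult:
    """Generate and analyse a full synthetic study.

    With ``outdir`` set, every stage's artifact is written (plates, profile
    TSVs, edge lists, partitions, centrality tables, enrichment tables) and
    hashed into manifest.json; otherwise the run stays in memory.
    """
    config = config or StudyConfig()
    t0 = time.time()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
        "artifacts": {},
    }

    library = generate_library(config.n_genes, config.density, seed=config.seed)
    truth = study_truth(
        library,
        seed=_cell_seed(config.seed, 0),
        effect_size=config.effect_size,
        noise_cv=config.noise_cv,
        backgrounds=config.backgrounds,
        probes=config.probes,
        hit_design=config.hit_design,
        linkage_window_bp=config.scoring.linkage_window_bp,
    )
    n_global = max(config.global_n_genes, config.n_genes)
    global_genes = [gene_name(i) for i in range(n_global)]
    global_gin, partition = generate_global_gin(
        n_global, config.n_blocks, config.p_in, config.p_out,
        seed=_cell_seed(config.seed, 1), genes=global_genes,
    )
    truth.planted_partition = partition
    dag, annotations = generate_go(
        global_genes, config.go_terms, config.go_depth, config.go_rate,
        seed=_cell_seed(config.seed, 2), partition=partition,
        bias=config.go_bias,
    )

    cells = [(b, p) for b in config.backgrounds for p in config.probes]
    profiles, gins, partitions = {}, {}, {}
    coverage, centrality, scans, tops, boots, enrich, safe = (
        {}, {}, {}, {}, {}, {}, {}
    )
    for i, (bg, probe) in enumerate(cells):
        cseed = _cell_seed(config.seed, 10 + i)
        control, treated = generate_screen_pair(
            library, truth, bg, probe, inhibition=config.inhibition, seed=cseed
        )
        control = [normalize_plate(p) for p in control]
        treated = [normalize_plate(p) for p in treated]
        ratios = compute_ratios(treated, control)
        profile = score_profile(ratios, config.scoring, background=bg, probe=probe)
        if config.probes[probe] == "query":
            profile = exclude_linkage(
                profile, truth.query_genes[probe], library
            )
        profiles[(bg, probe)] = profile

        seeds = profile.hits
        gin = build_augmented_gin(
            seeds, global_gin, config.hop_bound,
            config.weight_cutoff, config.p_cutoff,
        )
        gins[(bg, probe)] = gin
        part = louvain_partition(gin, seed=cseed,
                                 resolution=config.louvain_resolution)
        partitions[(bg, probe)] = part
        coverage[(bg, probe)] = community_go_coverage(
            part, annotations, set(gin.nodes)
        )

        table = compute_centralities(gin)
        if config.run_cluster_scan and len(table) > 10:
            scans[(bg, probe)] = optimize_cluster_count(table, seed=cseed)
        table = assign_centrality_clusters(table, k=config.k_clusters, seed=cseed)
        centrality[(bg, probe)] = table
        tops[(bg, probe)] = top_bottleneck_genes(table, "BC", config.top_n)
        boots[(bg, probe)] = bootstrap_centrality_test(
            gin, seeds, metric="BC", n_boot=config.n_boot, seed=cseed
        )

        # GO enrichment of the bottleneck (max-mean-BC) centrality cluster
        delta_genes = set(table.index[table["cluster"] == table["cluster"].iloc[
            int(np.argmax(table["BC"].to_numpy()))]])
        pop = set(gin.nodes)
        study = delta_genes & pop
        if study:
            res = hypergeom_enrich(study, pop, annotations)
            sig_terms = list(res.index[res["significant"]])
            if sig_terms and dag.ic:
                res = res.join(uniqueness_table(sig_terms, dag), how="left")
            enrich[(bg, probe)] = res

        if config.include_safe:
            pos = _layout(gin, seed=cseed)
            lengths = [
                float(np.hypot(*(np.asarray(pos[u]) - np.asarray(pos[v]))))
                for u, v in gin.edges
            ]
            med = float(np.median(lengths)) if lengths else 1.0
            factor = config.safe_median_edge_length / med if med > 0 else 1.0
            emb = {n: (x * factor, y * factor) for n, (x, y) in pos.items()}
            safe[(bg, probe)] = safe_enrichment(
                gin, emb, annotations,
                SafeConfig(radius=config.safe_radius, alpha=config.safe_alpha),
            )

        manifest["stages"][f"{bg}:{probe}"] = {
            "seed": cseed,
            "n_hits": len(seeds),
            "gin_nodes": gin.number_of_nodes(),
            "gin_edges": gin.number_of_edges(),
            "n_communities": part.n_communities,
            "modularity": part.modularity,
            "bootstrap_p": boots[(bg, probe)].p,
            "bootstrap_included": boots[(bg, probe)].included,
        }

        if out is not None:
            cell_dir = out / f"{bg}__{probe}"
            cell_dir.mkdir(exist_ok=True)
            profile.to_tsv(cell_dir / "profile.tsv")
            gio.write_edgelist(gin, cell_dir / "augmented_gin.tsv")
            part.to_tsv(cell_dir / "communities.tsv")
            table.reset_index().to_csv(
                cell_dir / "centrality.tsv", sep="\t", index=False
            )

    # cross-cell analyses
    hit_reports = {}
    for probe in config.probes:
        cell_profiles = [profiles[(b, probe)] for b in config.backgrounds]
        if len(cell_profiles) >= 2:
            hit_reports[probe] = hit_set_algebra(cell_profiles)

    profile_clustering = None
    if len(profiles) >= 3:
        matrix = build_profile_matrix(list(profiles.values()))
        profile_clustering = hierarchical_cluster(
            matrix, n_clades=config.n_clades
        )
        profile_clustering["matrix"] = matrix

    if out is not None:
        gio.write_edgelist(global_gin, out / "global_gin.tsv")
        gio.write_gmt(annotations, out / "annotations.gmt")
        dag.to_tsv(out / "go_terms.tsv")
        gio.write_truth_json(truth, out / "truth.json")
        if profile_clustering is not None:
            (out / "profiles.nwk").write_text(profile_clustering["newick"])
        for f in sorted(out.rglob("*")):
            if f.is_file() and f.name != "manifest.json":
                manifest["artifacts"][str(f.relative_to(out))] = _sha256(f)

    manifest["runtime_s"] = time.time() - t0
    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))

    return StudyResult(
        config=config,
        library=library,
        truth=truth,
        global_gin=global_gin,
        dag=dag,
        annotations=annotations,
        profiles=profiles,
        hit_reports=hit_reports,
        profile_clustering=profile_clustering,
        gins=gins,
        partitions=partitions,
        coverage=coverage,
        centrality=centrality,
        cluster_scans=scans,
        top_genes=tops,
        bootstrap=boots,
        enrichment=enrich,
        safe=safe,
        manifest=manifest,
    )


def validate_inputs(paths: dict) -> dict:
    """Schema and consistency checks over a study's input files.

    ``paths`` may contain 'plates' (list of CSV paths), 'global_gin' (edge
    TSV), 'annotations' (GMT) and 'go_terms' (term TSV).  Returns a report
    with 'failures' (schema violations) and 'warnings' (e.g. screen genes
    absent from the global network); an empty failure list means the bundle
    validates.
    """
    failures, warns = [], []
    screen_genes: set[str] = set()
    for p in paths.get("plates", []):
        try:
            plates = gio.read_plates_csv(p)
            for pl in plates:
                screen_genes |= {g for g in pl.genes.values() if g}
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            failures.append(f"{p}: {exc}")
    net_genes: set[str] = set()
    if "global_gin" in paths:
        try:
            g = gio.read_edgelist(paths["global_gin"])
            net_genes = set(g.nodes)
        except Exception as exc:
            failures.append(f"{paths['global_gin']}: {exc}")
    ann_genes: set[str] = set()
    if "annotations" in paths:
        try:
            ann = gio.read_gmt(paths["annotations"])
            ann_genes = set(ann)
        except Exception as exc:
            failures.append(f"{paths['annotations']}: {exc}")
    if "go_terms" in paths:
        try:
            from .enrichment import GODag

            GODag.from_tsv(paths["go_terms"])
        except Exception as exc:
            failures.append(f"{paths['go_terms']}: {exc}")

    if screen_genes and net_genes:
        missing = screen_genes - net_genes
        if missing:
            warns.append(
                f"{len(missing)} screen gene(s) absent from the global GIN"
            )
    if net_genes and ann_genes:
        missing = net_genes - ann_genes
        if missing:
            warns.append(f"{len(missing)} network gene(s) without annotation")
    return {"failures": failures, "warnings": warns}
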