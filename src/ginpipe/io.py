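"""Readers/writers for the pipeline's plain-text interchange formats.

Plates travel as CSV (plate,row,col,gene,size,border_flag); networks as
edge-list TSV (gene_a,gene_b,weight,p), GraphML, or a sparse MatrixMarket
adjacency with a node-order sidecar; annotations as GMT; the term DAG as a
(child,parent,namespace,name) TSV; ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd
import scipy.io
import scipy.sparse

from .scoring import ColonyPlate, InteractionProfile, Position, ScoringConfig

__all__ = [
    "write_plates_csv",
    "read_plates_csv",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
    "write_adjacency_mtx",
    "read_adjacency_mtx",
    "write_gmt",
    "read_gmt",
    "write_truth_json",
    "read_truth_json",
    "read_profile_tsv",
]


def write_plates_csv(plates: list[ColonyPlate], path) -> None:
    rows = []
    for pl in plates:
        for pos, size in sorted(pl.grid.items()):
            rows.append(
                {
                    "plate": pos.plate,
                    "row": pos.row,
                    "col": pos.col,
                    "gene": pl.genes.get(pos) or "",
                    "size": size,
                    "border_flag": int(pl.border_flags.get(pos, False)),
                    "condition": pl.condition,
                    "background": pl.background,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plates_csv(path) -> list[ColonyPlate]:
    df = pd.read_csv(path, dtype={"gene": str}, keep_default_na=False)
    required = {"plate", "row", "col", "gene", "size", "border_flag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    plates = []
    for pid, sub in df.groupby("plate"):
        grid, genes, border = {}, {}, {}
        for r in sub.itertuples(index=False):
            pos = Position(int(r.plate), int(r.row), int(r.col))
            grid[pos] = float(r.size)
            genes[pos] = r.gene or None
            border[pos] = bool(int(r.border_flag))
        plates.append(
            ColonyPlate(
                int(pid),
                getattr(sub.iloc[0], "condition", ""),
                getattr(sub.iloc[0], "background", ""),
                grid,
                genes,
                border,
            )
        )
    return plates


def write_edgelist(gin: nx.Graph, path) -> None:
    rows = [
        {
            "gene_a": u,
            "gene_b": v,
            "weight": d.get("weight", 1.0),
            "p": d.get("p", 0.0),
        }
        for u, v, d in gin.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight", "p"])
    df.sort_values(["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_edgelist(path, nodes=None) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str},
                     float_precision="round_trip")
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for r in df.itertuples(index=False):
        g.add_edge(r.gene_a, r.gene_b, weight=float(r.weight), p=float(r.p))
    return g


def write_graphml(gin: nx.Graph, path) -> None:
    nx.write_graphml(gin, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_adjacency_mtx(gin: nx.Graph, prefix) -> None:
    """Sparse |A| as <prefix>.mtx plus node order in <prefix>.nodes.tsv."""
    nodes = sorted(gin.nodes, key=str)
    idx = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, d in gin.edges(data=True):
        w = d.get("weight", 1.0)
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
        vals += [w, w]
    a = scipy.sparse.coo_matrix(
        (vals, (rows, cols)), shape=(len(nodes), len(nodes))
    )
    scipy.io.mmwrite(str(prefix) + ".mtx", a)
    pd.DataFrame({"gene": nodes}).to_csv(
        str(prefix) + ".nodes.tsv", sep="\t", index=False
    )


def read_adjacency_mtx(prefix) -> nx.Graph:
    a = scipy.io.mmread(str(prefix) + ".mtx").tocoo()
    nodes = pd.read_csv(str(prefix) + ".nodes.tsv", sep="\t")["gene"].tolist()
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, j, w in zip(a.row, a.col, a.data):
        if i < j:
            g.add_edge(nodes[i], nodes[j], weight=float(w))
    return g


def write_gmt(annotations: dict[str, set[str]], path, description: str = "") -> None:
    """gene -> terms mapping written as a GMT (one row per term)."""
    by_term: dict[str, set[str]] = {}
    for g, terms in annotations.items():
        for t in terms:
            by_term.setdefault(t, set()).add(g)
    with open(path, "w") as fh:
        for t in sorted(by_term):
            genes = "\t".join(sorted(by_term[t]))
            fh.write(f"{t}\t{description}\t{genes}\n")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT file to gene -> terms mapping."""
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, genes = parts[0], parts[2:]
            for g in genes:
                if g:
                    annotations.setdefault(g, set()).add(term)
    return annotations


def write_truth_json(truth, path) -> None:
    payload = {
        "effect_size": truth.effect_size,
        "noise_cv": truth.noise_cv,
        "query_genes": truth.query_genes,
        "planted_partition": truth.planted_partition,
        "planted_hits": {
            f"{b}|{p}": sorted(genes)
            for (b, p), genes in truth.planted_hits.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_json(path):
    from .synthetic import SyntheticTruth

    payload = json.loads(Path(path).read_text())
    hits = {}
    for key, genes in payload["planted_hits"].items():
        b, p = key.split("|", 1)
        hits[(b, p)] = set(genes)
    return SyntheticTruth(
        planted_hits=hits,
        effect_size=payload["effect_size"],
        noise_cv=payload["noise_cv"],
        planted_partition={k: int(v) for k, v in payload["planted_partition"].items()},
        query_genes=payload["query_genes"],
    )


def read_profile_tsv(path, background: str = "", probe: str = "") -> InteractionProfile:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}).set_index("gene")
    return InteractionProfile(background, probe, df, ScoringConfig())
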