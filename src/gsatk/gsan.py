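"""Gene-set association network (GSAN) construction and export.

A GSAN is an undirected graph whose nodes are gene sets and whose edges are
overlap associations between them. Candidate edges are all pairs sharing at
least one gene; each is scored by the blended Jaccard/cover similarity and,
optionally, tested for over-representation of the shared genes with a
one-sided Fisher's exact test (the smaller set treated as the "query"
against the larger, under a configurable gene universe), with
Benjamini-Hochberg FDR over all candidates. Retained edges satisfy the
similarity floor and, when the Fisher filter is on, both p and FDR
thresholds.

Node attributes map to the conventional rendering: scale → node size,
NORM_ABS_FC → node color, data source → node line color; edge score →
edge width. Exports (node/edge tables, SIF, GraphML) are Cytoscape-ready
and byte-stable across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .enrichment import bh_fdr, fisher_pvalue
from .expression import ExpressionTable, NormParams, norm_abs_fc
from .genesets import GeneSet
from .similarity import (
    SimilarityEdge,
    SimilarityParams,
    overlapping_pairs,
    _edge as _score_edge,
)

__all__ = [
    "GSANNode",
    "GSANEdge",
    "GSANGraph",
    "build_gsan",
    "annotate_expression",
    "export_graph",
    "read_graph_tables",
    "to_networkx",
]

DEFAULT_MIN_SIMILARITY = 0.1


@dataclass(frozen=True)
class GSANNode:
    set_id: str
    name: str
    source: str
    scale: int
    norm_abs_fc: float | None = None


@dataclass(frozen=True)
class GSANEdge:
    """A similarity edge annotated with the edge-level Fisher test."""

    set_i: str
    set_j: str
    overlap: int
    union_size: int
    s_l: float
    s_r: float
    score: float
    p_value: float | None = None
    fdr: float | None = None

    @property
    def similarity(self) -> SimilarityEdge:
        return SimilarityEdge(
            self.set_i, self.set_j, self.overlap, self.union_size,
            self.s_l, self.s_r, self.score,
        )


@dataclass
class GSANGraph:
    nodes: list[GSANNode]
    edges: list[GSANEdge]
    params: dict = field(default_factory=dict)

    def node_ids(self) -> list[str]:
        return [n.set_id for n in self.nodes]

    def isolated_nodes(self) -> list[str]:
        touched = {e.set_i for e in self.edges} | {e.set_j for e in self.edges}
        return [n.set_id for n in self.nodes if n.set_id not in touched]


def build_gsan(
    sets: Sequence[GeneSet],
    params: SimilarityParams | None = None,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    fisher_filter: bool = True,
    universe_size: int | str = "auto",
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
) -> GSANGraph:
    """Build the association network over the given gene sets.

    ``universe_size="auto"`` uses the union of the input sets' genes as the
    background for edge-level Fisher tests. Every input set appears as a
    node; sets losing all their edges to the filters remain as isolates.
    """
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("a GSAN needs at least 2 gene sets")
    ids = [s.set_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate set_ids among GSAN input sets")
    params = params or SimilarityParams()

    if universe_size == "auto":
        union: set[str] = set()
        for s in sets:
            union |= s.genes
        universe_n = len(union)
    else:
        universe_n = int(universe_size)

    candidates: list[GSANEdge] = []
    for i, j, ov in overlapping_pairs(sets):
        a, b = sets[i], sets[j]
        if a.set_id > b.set_id:
            a, b = b, a
        sim = _score_edge(a.set_id, a.scale, b.set_id, b.scale, ov, params.alpha)
        candidates.append(
            GSANEdge(
                sim.set_i, sim.set_j, sim.overlap, sim.union_size,
                sim.s_l, sim.s_r, sim.score,
            )
        )
    candidates.sort(key=lambda e: (e.set_i, e.set_j))

    if fisher_filter and candidates:
        scales = {s.set_id: s.scale for s in sets}
        pvals = []
        for e in candidates:
            small = min(scales[e.set_i], scales[e.set_j])
            large = max(scales[e.set_i], scales[e.set_j])
            pvals.append(fisher_pvalue(e.overlap, small, large, universe_n))
        fdrs = bh_fdr(pvals)
        candidates = [
            replace(e, p_value=p, fdr=f)
            for e, p, f in zip(candidates, pvals, fdrs)
        ]
        kept = [
            e
            for e in candidates
            if e.score >= min_similarity
            and e.p_value < p_threshold
            and e.fdr < fdr_threshold
        ]
    else:
        kept = [e for e in candidates if e.score >= min_similarity]

    nodes = sorted(
        (GSANNode(s.set_id, s.name, s.source, s.scale) for s in sets),
        key=lambda n: n.set_id,
    )
    return GSANGraph(
        nodes=nodes,
        edges=kept,
        params={
            "alpha": params.alpha,
            "min_similarity": min_similarity,
            "fisher_filter": fisher_filter,
            "universe_size": universe_n,
            "p_threshold": p_threshold,
            "fdr_threshold": fdr_threshold,
        },
    )


def annotate_expression(
    graph: GSANGraph,
    sets: Sequence[GeneSet],
    expr: ExpressionTable,
    params: NormParams | None = None,
) -> GSANGraph:
    """Populate node NORM_ABS_FC from an expression table.

    Nodes whose gene set has no measured gene keep an undefined (None)
    score. ``sets`` must cover every node id (the graph stores memberships
    only through its nodes, so the originating sets are re-supplied here).
    """
    params = params or NormParams()
    by_id = {s.set_id: s for s in sets}
    missing = [n.set_id for n in graph.nodes if n.set_id not in by_id]
    if missing:
        raise ValueError(f"no gene set supplied for nodes: {missing}")
    nodes = [
        replace(n, norm_abs_fc=norm_abs_fc(by_id[n.set_id], expr, params))
        for n in graph.nodes
    ]
    return GSANGraph(nodes=nodes, edges=list(graph.edges), params=dict(graph.params))


# ---------------------------------------------------------------------------
# Export / import

_NODE_COLS = ["set_id", "name", "source", "scale", "norm_abs_fc"]
_EDGE_COLS = ["set_i", "set_j", "overlap", "union_size", "s_l", "s_r",
              "score", "p_value", "fdr"]


def _node_frame(graph: GSANGraph) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (n.set_id, n.name, n.source, n.scale,
             math.nan if n.norm_abs_fc is None else n.norm_abs_fc)
            for n in graph.nodes
        ],
        columns=_NODE_COLS,
    )


def _edge_frame(graph: GSANGraph) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.set_i, e.set_j, e.overlap, e.union_size, e.s_l, e.s_r, e.score,
             math.nan if e.p_value is None else e.p_value,
             math.nan if e.fdr is None else e.fdr)
            for e in graph.edges
        ],
        columns=_EDGE_COLS,
    )


def to_networkx(graph: GSANGraph) -> nx.Graph:
    g = nx.Graph()
    for n in graph.nodes:
        g.add_node(
            n.set_id,
            name=n.name,
            source=n.source,
            scale=n.scale,
            norm_abs_fc=math.nan if n.norm_abs_fc is None else float(n.norm_abs_fc),
        )
    for e in graph.edges:
        g.add_edge(
            e.set_i, e.set_j,
            overlap=e.overlap, union_size=e.union_size,
            s_l=e.s_l, s_r=e.s_r, score=e.score,
            p_value=math.nan if e.p_value is None else float(e.p_value),
            fdr=math.nan if e.fdr is None else float(e.fdr),
        )
    return g


def export_graph(
    graph: GSANGraph,
    out_prefix: str | Path,
    formats: Sequence[str] = ("tables", "sif", "graphml"),
) -> list[Path]:
    """Write the graph in the requested formats.

    ``tables`` → ``<prefix>.nodes.tsv`` + ``<prefix>.edges.tsv``;
    ``sif`` → one ``a gsan b`` line per edge plus bare lines for isolated
    nodes; ``graphml`` → attribute-carrying XML readable by Cytoscape.
    """
    if not graph.nodes:
        raise ValueError("cannot export an empty graph")
    prefix = Path(out_prefix)
    written: list[Path] = []
    for fmt in formats:
        if fmt == "tables":
            np_, ep_ = Path(f"{prefix}.nodes.tsv"), Path(f"{prefix}.edges.tsv")
            # %.17g keeps full double precision so tables round-trip exactly
            _node_frame(graph).to_csv(np_, sep="\t", index=False,
                                      float_format="%.17g")
            _edge_frame(graph).to_csv(ep_, sep="\t", index=False,
                                      float_format="%.17g")
            written += [np_, ep_]
        elif fmt == "sif":
            sp = Path(f"{prefix}.sif")
            with sp.open("w") as fh:
                for e in graph.edges:
                    fh.write(f"{e.set_i}\tgsan\t{e.set_j}\n")
                for nid in graph.isolated_nodes():
                    fh.write(f"{nid}\n")
            written.append(sp)
        elif fmt == "graphml":
            gp = Path(f"{prefix}.graphml")
            nx.write_graphml(to_networkx(graph), gp)
            written.append(gp)
        else:
            raise ValueError(f"unknown export format {fmt!r}")
    return written


def read_graph_tables(out_prefix: str | Path) -> GSANGraph:
    """Reconstruct a graph from the node/edge tables written by export_graph."""
    prefix = Path(out_prefix)
    ndf = pd.read_csv(f"{prefix}.nodes.tsv", sep="\t",
                      float_precision="round_trip")
    edf = pd.read_csv(f"{prefix}.edges.tsv", sep="\t",
                      float_precision="round_trip")
    nodes = [
        GSANNode(
            set_id=str(r.set_id), name=str(r.name), source=str(r.source),
            scale=int(r.scale),
            norm_abs_fc=None if pd.isna(r.norm_abs_fc) else float(r.norm_abs_fc),
        )
        for r in ndf.itertuples()
    ]
    edges = [
        GSANEdge(
            set_i=str(r.set_i), set_j=str(r.set_j), overlap=int(r.overlap),
            union_size=int(r.union_size), s_l=float(r.s_l), s_r=float(r.s_r),
            score=float(r.score),
            p_value=None if pd.isna(r.p_value) else float(r.p_value),
            fdr=None if pd.isna(r.fdr) else float(r.fdr),
        )
        for r in edf.itertuples()
    ]
    return GSANGraph(nodes=nodes, edges=edges)
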