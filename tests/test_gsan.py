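import itertools

import pytest

from gsatk.enrichment import bh_fdr, fisher_pvalue
from gsatk.expression import ExpressionTable, NormParams
from gsatk.gsan import (
    annotate_expression,
    build_gsan,
    export_graph,
    read_graph_tables,
    to_networkx,
)
from gsatk.similarity import SimilarityParams, similarity
from gsatk.synth import ScaleLaw, SynthSpec, generate_collection

from conftest import make_set


def brute_force_edges(sets, alpha=0.8, min_sim=0.1, fisher=True,
                      p_thr=0.05, fdr_thr=0.05, universe=None):
    """Oracle: enumerate every pair, apply the same thresholds independently."""
    if universe is None:
        universe = len(set().union(*(s.genes for s in sets)))
    cands = []
    for a, b in itertools.combinations(sorted(sets, key=lambda s: s.set_id), 2):
        ov = len(a.genes & b.genes)
        if ov < 1:
            continue
        e = similarity(a, b, SimilarityParams(alpha))
        small, large = min(a.scale, b.scale), max(a.scale, b.scale)
        p = fisher_pvalue(ov, small, large, universe)
        cands.append((a.set_id, b.set_id, e.score, p))
    if not cands:
        return set()
    fdrs = bh_fdr([c[3] for c in cands])
    kept = set()
    for (i, j, score, p), f in zip(cands, fdrs):
        if score >= min_sim and (not fisher or (p < p_thr and f < fdr_thr)):
            kept.add((i, j))
    return kept


@pytest.fixture
def random_sets():
    spec = SynthSpec(seed=21, universe_size=300, n_sets=40,
                     scale_law=ScaleLaw(min_scale=10, max_scale=80),
                     overlap_model="block-community")
    return list(generate_collection(spec))


class TestBuildGsan:
    def test_two_identical_sets_single_edge(self):
        sets = [make_set("a", ["X", "Y", "Z"]), make_set("b", ["X", "Y", "Z"])]
        g = build_gsan(sets, fisher_filter=False, min_similarity=0.0)
        assert len(g.edges) == 1
        assert g.edges[0].score == 1.0

    def test_disjoint_sets_all_isolated(self):
        sets = [make_set(f"s{i}", [f"g{i}a", f"g{i}b"]) for i in range(4)]
        g = build_gsan(sets)
        assert g.edges == []
        assert sorted(g.isolated_nodes()) == sorted(s.set_id for s in sets)

    def test_four_set_fixture_matches_exhaustive_oracle(self):
        sets = [
            make_set("a", ["A", "B", "C", "D"]),
            make_set("b", ["C", "D", "E"]),
            make_set("c", ["E", "F"]),
            make_set("d", ["X", "Y"]),
        ]
        g = build_gsan(sets, min_similarity=0.1, fisher_filter=True)
        got = {(e.set_i, e.set_j) for e in g.edges}
        assert got == brute_force_edges(sets)

    def test_random_fixture_matches_exhaustive_oracle(self, random_sets):
        for fisher in (True, False):
            g = build_gsan(random_sets, fisher_filter=fisher)
            got = {(e.set_i, e.set_j) for e in g.edges}
            assert got == brute_force_edges(random_sets, fisher=fisher)

    def test_no_filters_equals_all_overlapping_pairs(self, random_sets):
        g = build_gsan(random_sets, min_similarity=0.0, fisher_filter=False)
        got = {(e.set_i, e.set_j) for e in g.edges}
        expected = brute_force_edges(random_sets, min_sim=0.0, fisher=False)
        assert got == expected

    def test_raising_thresholds_never_adds_edges(self, random_sets):
        base = build_gsan(random_sets, min_similarity=0.05)
        stricter = build_gsan(random_sets, min_similarity=0.3)
        b = {(e.set_i, e.set_j) for e in base.edges}
        s = {(e.set_i, e.set_j) for e in stricter.edges}
        assert s <= b
        tighter_fdr = build_gsan(random_sets, min_similarity=0.05,
                                 p_threshold=0.01, fdr_threshold=0.01)
        assert {(e.set_i, e.set_j) for e in tighter_fdr.edges} <= b

    def test_input_order_invariance(self, random_sets):
        g1 = build_gsan(random_sets)
        g2 = build_gsan(list(reversed(random_sets)))
        assert g1.nodes == g2.nodes
        assert g1.edges == g2.edges

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            build_gsan([make_set("a", ["X"])])

    def test_edge_endpoints_exist_among_nodes(self, random_sets):
        g = build_gsan(random_sets, min_similarity=0.0, fisher_filter=False)
        ids = set(g.node_ids())
        for e in g.edges:
            assert e.set_i in ids and e.set_j in ids
            assert e.set_i != e.set_j


class TestAnnotateExpression:
    def test_full_coverage_annotates_every_node(self):
        sets = [make_set("a", ["X", "Y"]), make_set("b", ["Y", "Z"])]
        expr = ExpressionTable.from_records(
            [("X", 2.0), ("Y", 1.0), ("Z", 4.0)], with_pvalues=False)
        g = annotate_expression(build_gsan(sets, fisher_filter=False),
                                sets, expr, NormParams(6))
        assert all(n.norm_abs_fc is not None for n in g.nodes)

    def test_uncovered_node_undefined(self):
        sets = [make_set("a", ["X", "Y"]), make_set("b", ["Q1", "Q2"])]
        expr = ExpressionTable.from_records([("X", 2.0), ("Y", 1.0)],
                                            with_pvalues=False)
        g = annotate_expression(build_gsan(sets, fisher_filter=False),
                                sets, expr)
        by_id = {n.set_id: n for n in g.nodes}
        assert by_id["a"].norm_abs_fc is not None
        assert by_id["b"].norm_abs_fc is None

    def test_planted_high_fc_node_is_maximal(self):
        sets = [make_set("hot", ["H1", "H2"]), make_set("cold", ["C1", "C2"]),
                make_set("mix", ["H1", "C1"])]
        expr = ExpressionTable.from_records(
            [("H1", 9.0), ("H2", 8.0), ("C1", 1.0), ("C2", 1.1)],
            with_pvalues=False)
        g = annotate_expression(build_gsan(sets, fisher_filter=False,
                                           min_similarity=0.0),
                                sets, expr)
        scores = {n.set_id: n.norm_abs_fc for n in g.nodes}
        assert max(scores, key=scores.get) == "hot"


class TestExport:
    def test_sif_line_per_edge_plus_isolates(self, tmp_path):
        sets = [make_set("a", ["X", "Y"]), make_set("b", ["Y", "Z"]),
                make_set("iso", ["Q1", "Q2"])]
        g = build_gsan(sets, fisher_filter=False, min_similarity=0.0)
        export_graph(g, tmp_path / "net", formats=("sif",))
        lines = (tmp_path / "net.sif").read_text().splitlines()
        assert "a\tgsan\tb" in lines
        assert "iso" in lines
        assert len(lines) == 2

    def test_tables_round_trip_to_identical_graph(self, tmp_path, random_sets):
        g = build_gsan(random_sets, min_similarity=0.0, fisher_filter=True,
                       p_threshold=1.1, fdr_threshold=1.1)
        export_graph(g, tmp_path / "net", formats=("tables",))
        back = read_graph_tables(tmp_path / "net")
        assert back.nodes == g.nodes
        assert back.edges == g.edges

    def test_graphml_preserves_structure(self, tmp_path, random_sets):
        import networkx as nx

        g = build_gsan(random_sets)
        export_graph(g, tmp_path / "net", formats=("graphml",))
        back = nx.read_graphml(tmp_path / "net.graphml")
        ref = to_networkx(g)
        assert set(back.nodes) == set(ref.nodes)
        assert {frozenset(e) for e in back.edges} == {
            frozenset(e) for e in ref.edges}

    def test_unknown_format_rejected(self, tmp_path, random_sets):
        g = build_gsan(random_sets)
        with pytest.raises(ValueError):
            export_graph(g, tmp_path / "net", formats=("xml",))

    def test_exports_byte_stable(self, tmp_path, random_sets):
        g1 = build_gsan(random_sets)
        g2 = build_gsan(random_sets)
        export_graph(g1, tmp_path / "r1", formats=("tables", "sif"))
        export_graph(g2, tmp_path / "r2", formats=("tables", "sif"))
        for suffix in (".nodes.tsv", ".edges.tsv", ".sif"):
            assert (tmp_path / f"r1{suffix}").read_bytes() == \
                   (tmp_path / f"r2{suffix}").read_bytes()
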