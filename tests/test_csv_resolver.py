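"""Anchor selection, DAG construction, path solving and signature naming."""

import numpy as np
import pytest

from csvarc import csv_resolver as cr
from csvarc import simdata as sd
from csvarc.csv_resolver import PathGraph, ResolverParams
from csvarc.records import AlignmentRecord, CsvTemplate, VariantCall


def rec(qs, qe, ts, te, cigar, strand="+", qlen=100_000, tlen=300_000, qname="q",
        tname="chr1"):
    return AlignmentRecord(qname, qs, qe, qlen, strand, tname, ts, te, tlen,
                           cigar, 60).validate()


class TestAnchors:
    def test_long_exact_record_is_anchor(self):
        r = rec(0, 10_000, 0, 10_000, [(10_000, "=")])
        assert cr.select_anchors([r]) == [r]

    def test_short_record_is_not_anchor_at_defaults(self):
        r = rec(0, 200, 0, 200, [(200, "=")])
        assert cr.select_anchors([r]) == []

    def test_zero_thresholds_make_all_records_anchors(self):
        rs = [rec(0, 200, 0, 200, [(200, "=")]),
              rec(300, 400, 300, 400, [(50, "="), (50, "X")])]
        params = ResolverParams(anchor_min_len=0, anchor_min_identity=0.0)
        assert cr.select_anchors(rs, params) == rs

    def test_low_identity_record_is_not_anchor(self):
        r = rec(0, 10_000, 0, 10_000, [(8_000, "="), (2_000, "X")])
        assert cr.select_anchors([r]) == []


def brute_force_best(graph: PathGraph):
    """Exhaustively enumerate source->sink paths; min over (cost, edges, path)."""
    best = None
    by_pair = {}
    for u, v, cost, _ in graph.edges:
        by_pair.setdefault(u, []).append((v, cost))

    def dfs(u, cost, n_edges, path):
        nonlocal best
        if u == graph.sink:
            key = (cost, n_edges, tuple(path))
            if best is None or key < best:
                best = key
            return
        for v, ecost in by_pair.get(u, []):
            node = graph.node_cost[v] if v != graph.sink else 0.0
            dfs(v, cost + ecost + node, n_edges + 1,
                path + ([v] if v < len(graph.records) else []))

    dfs(graph.source, 0.0, 0, [])
    return best


def random_graph(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    node_cost = list(np.round(rng.uniform(-3, 1, size=n), 3))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                edges.append((i, j, float(np.round(rng.uniform(0, 5), 3)), []))
    anchors = [i for i in range(n) if rng.random() < 0.5] or [0]
    for i in anchors:
        edges.append((n, i, 0.0, []))
        edges.append((i, n + 1, 0.0, []))
    return PathGraph([None] * n, node_cost + [0.0, 0.0], edges, n, n + 1)


class TestSolver:
    def test_single_path_graph_returns_it(self):
        g = PathGraph([None] * 2, [0.5, -1.0, 0.0, 0.0],
                      [(2, 0, 0.0, []), (0, 1, 1.0, []), (1, 3, 0.0, [])], 2, 3)
        res = cr.solve_optimal_path(g)
        assert res.path == [0, 1]
        assert res.cost == pytest.approx(0.5)

    def test_diamond_picks_cheaper_branch(self):
        # source -> 0 -> {1 (cost 5) | 2 (cost 7)} -> 3 -> sink
        edges = [
            (4, 0, 0.0, []), (0, 1, 5.0, []), (0, 2, 7.0, []),
            (1, 3, 0.0, []), (2, 3, 0.0, []), (3, 5, 0.0, []),
        ]
        g = PathGraph([None] * 4, [0.0] * 6, edges, 4, 5)
        res = cr.solve_optimal_path(g)
        assert res.path == [0, 1, 3]
        assert res.cost == pytest.approx(5.0)

    def test_unreachable_sink_returns_none(self):
        g = PathGraph([None] * 2, [0.0] * 4, [(2, 0, 0.0, [])], 2, 3)
        assert cr.solve_optimal_path(g) is None

    @pytest.mark.parametrize("bellman_ford", [False, True])
    def test_matches_exhaustive_enumeration_on_random_dags(self, bellman_ford):
        checked = 0
        for seed in range(100):
            g = random_graph(seed)
            expected = brute_force_best(g)
            got = cr.solve_optimal_path(g, bellman_ford=bellman_ford)
            if expected is None:
                assert got is None
                continue
            checked += 1
            assert got.cost == pytest.approx(expected[0], abs=1e-9)
            assert tuple(got.path) == expected[2]
        assert checked >= 80  # nearly all random graphs reach the sink


class TestGraphConstruction:
    def test_colinear_records_form_a_chain_path(self):
        recs = [rec(i * 2000, (i + 1) * 2000, i * 2000 + 100 * i,
                    (i + 1) * 2000 + 100 * i, [(2000, "=")]) for i in range(4)]
        params = ResolverParams()
        graph = cr.build_variant_graph(recs, {}, {}, params)
        res = cr.solve_optimal_path(graph)
        assert res.path == [0, 1, 2, 3]

    def test_two_records_one_variant_edge(self):
        a = rec(0, 2000, 0, 2000, [(2000, "=")])
        b = rec(2000, 4000, 2500, 4500, [(2000, "=")])
        dv = VariantCall("DEL", "chr1", 2000, 2500, 500, source="inter")
        graph = cr.build_variant_graph([a, b], {}, {(0, 1): [dv]})
        (edge,) = [e for e in graph.edges if e[0] == 0 and e[1] == 1]
        assert edge[3] == [dv]
        assert edge[2] > ResolverParams().junction_open  # junction + variant cost

    def test_ambiguous_middle_gives_diamond_with_two_paths(self):
        a = rec(0, 2000, 0, 2000, [(2000, "=")])
        m1 = rec(2000, 2400, 3000, 3400, [(400, "=")])
        m2 = rec(2000, 2400, 5000, 5400, [(400, "=")])
        b = rec(2400, 4400, 6000, 8000, [(2000, "=")])
        graph = cr.build_variant_graph([a, m1, m2, b], {}, {})
        # oracle: enumerate paths; exactly two traverse a middle node
        paths = set()

        def dfs(u, path):
            if u == graph.sink:
                paths.add(tuple(path))
                return
            for idx in graph.adjacency.get(u, []):
                _, v, _, _ = graph.edges[idx]
                dfs(v, path + ([v] if v < 4 else []))

        dfs(graph.source, [])
        middles = {p for p in paths if len(p) == 3}
        assert {(0, 1, 3), (0, 2, 3)} <= middles

    def test_disconnected_record_does_not_change_the_path(self, ref300k):
        tpl = CsvTemplate("DEL-INV-DEL", [10_000, 20_000, 10_000])
        haps, truth = sd.implant_csv(ref300k, tpl, ("chr1", 100_000))
        recs = sd.simulate_alignments(ref300k, haps["h1"], truth, "h1")
        qseqs = {"chr1_h1": haps["h1"]["chr1"]}
        base = cr.resolve_complex(recs, ref300k.sequences, qseqs)
        # an irrelevant record on another target cannot join the graph
        stray = AlignmentRecord("chr1_h1", 5000, 7000, recs[0].query_len, "+",
                                "chrZ", 0, 2000, 2000, [(2000, "=")], 60)
        seqs = dict(ref300k.sequences)
        seqs["chrZ"] = haps["h1"]["chr1"][5000:7000]
        more = cr.resolve_complex(list(recs) + [stray], seqs, qseqs)
        assert [c.signature for c in more.csv_calls] == \
               [c.signature for c in base.csv_calls]
        assert more.csv_calls[0].span == base.csv_calls[0].span


class TestSignature:
    def variants(self, *specs):
        return [VariantCall(t, "chr1", p, p + ln if t != "INS" else p, ln,
                            source="inter") for t, p, ln in specs]

    def test_del_inv_del_signature(self):
        vs = self.variants(("DEL", 0, 10_000), ("INV", 10_000, 20_000),
                           ("DEL", 30_000, 10_000))
        call = cr.classify_csv_signature(vs, junction_count=2)
        assert call.signature == "DEL-INV-DEL"
        assert call.span == (0, 40_000)
        assert call.junction_count == 2

    def test_lone_inversion_is_simple(self):
        vs = self.variants(("INV", 10_000, 5_000))
        assert cr.classify_csv_signature(vs, junction_count=0) is None

    def test_single_junction_event_is_simple(self):
        vs = self.variants(("DEL", 0, 500), ("INS", 600, 80))
        assert cr.classify_csv_signature(vs, junction_count=1) is None

    def test_invdup_inv_invdup_signature(self):
        vs = self.variants(("INVDUP", 0, 5_000), ("INV", 5_000, 8_000),
                           ("INVDUP", 13_000, 5_000))
        call = cr.classify_csv_signature(vs, junction_count=2)
        assert call.signature == "INVDUP-INV-INVDUP"

    def test_small_indels_do_not_become_tokens(self):
        vs = self.variants(("DEL", 0, 10_000), ("INS", 5, 10), ("INV", 10_000, 20_000),
                           ("DEL", 30_000, 10_000))
        call = cr.classify_csv_signature(vs, junction_count=2)
        assert call.signature == "DEL-INV-DEL"


class TestEndToEnd:
    @pytest.mark.parametrize(
        "name", ["DEL-INV-DEL", "INVDUP-INV-DEL", "INVDUP-INV-INVDUP"]
    )
    def test_template_recovery_with_flanking_simple_variants(self, ref300k, name):
        tpl = CsvTemplate(name, [10_000, 20_000, 10_000])
        haps, truth = sd.implant_csv(ref300k, tpl, ("chr1", 120_000))
        recs = sd.simulate_alignments(ref300k, haps["h1"], truth, "h1")
        res = cr.resolve_complex(recs, ref300k.sequences,
                                 {"chr1_h1": haps["h1"]["chr1"]})
        assert [c.signature for c in res.csv_calls] == [name]
        got = [(v.vtype, v.pos, v.end) for v in res.csv_calls[0].variants if v.is_sv]
        want = [(v.vtype, v.pos, v.end) for v in truth.csv_events[0].expected_variants]
        assert got == want

    def test_csv_in_excluded_region_is_dropped(self, cen_ref):
        # the 400-kb array sits at [300k, 700k); put the CSV inside it
        tpl = CsvTemplate("DEL-INV-DEL", [10_000, 20_000, 10_000])
        haps, truth = sd.implant_csv(cen_ref, tpl, ("chr1", 400_000))
        recs = sd.simulate_alignments(cen_ref, haps["h1"], truth, "h1")
        exclusions = cen_ref.by_label("censat_exclude")
        res = cr.resolve_complex(recs, cen_ref.sequences,
                                 {"chr1_h1": haps["h1"]["chr1"]}, exclusions=exclusions)
        assert res.csv_calls == []
        assert [c.signature for c in res.dropped_csvs] == ["DEL-INV-DEL"]

    def test_no_anchor_records_skips_event(self, caplog):
        import logging

        r = rec(0, 200, 0, 200, [(200, "=")])
        with caplog.at_level(logging.WARNING):
            res = cr.resolve_complex([r], {"chr1": "A" * 300_000}, {"q": "A" * 200})
        assert res.csv_calls == [] and res.simple_variants == []
        assert any("no anchor" in m for m in caplog.messages)
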