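"""Trimming, intra/inter calling, exclusion filtering and replay."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csvarc import align_variants as av
from csvarc.records import AlignmentRecord, IntervalAnnotation, VariantCall, revcomp


def rec(qs, qe, ts, te, cigar, strand="+", qlen=10_000, tlen=10_000, qname="q",
        tname="t"):
    return AlignmentRecord(qname, qs, qe, qlen, strand, tname, ts, te, tlen,
                           cigar, 60).validate()


class TestTrimming:
    def test_disjoint_records_unchanged(self):
        a = rec(0, 100, 0, 100, [(100, "=")])
        b = rec(100, 200, 200, 300, [(100, "=")])
        out = av.trim_query_overlaps([a, b])
        assert [(r.query_start, r.query_end) for r in out] == [(0, 100), (100, 200)]

    def test_duplicate_record_dropped(self):
        a = rec(0, 100, 0, 100, [(100, "=")])
        b = rec(0, 100, 0, 100, [(100, "=")])
        assert len(av.trim_query_overlaps([a, b])) == 1

    def test_overlap_trimmed_from_record_with_fewer_matches(self):
        # records overlap by 10 query bases; a has mismatches there, b matches
        a = rec(0, 100, 0, 100, [(90, "="), (10, "X")])
        b = rec(90, 190, 200, 300, [(100, "=")])
        out = sorted(av.trim_query_overlaps([a, b]), key=lambda r: r.query_start)
        # oracle: trimming a loses 0 matches, trimming b loses 10 -> trim a
        assert out[0].query_end == 90 and out[0].cigar == [(90, "=")]
        assert out[1].query_start == 90

    def test_tie_trims_larger_target_coordinate(self):
        a = rec(0, 100, 500, 600, [(100, "=")])
        b = rec(90, 190, 0, 100, [(100, "=")])
        out = sorted(av.trim_query_overlaps([a, b]), key=lambda r: r.query_start)
        assert out[0].query_end == 90  # a (larger target_start) was trimmed

    def test_total_matches_never_increase_and_idempotent(self, rng):
        recs = []
        q = 0
        for _ in range(6):
            span = int(rng.integers(50, 200))
            start = max(0, q - int(rng.integers(0, 40)))
            t0 = int(rng.integers(0, 5000))
            recs.append(rec(start, start + span, t0, t0 + span, [(span, "=")]))
            q = start + span
        before = sum(r.matches for r in recs)
        once = av.trim_query_overlaps(recs)
        assert sum(r.matches for r in once) <= before
        twice = av.trim_query_overlaps(once)
        assert [(r.query_start, r.query_end, r.cigar) for r in once] == \
               [(r.query_start, r.query_end, r.cigar) for r in twice]
        # no query base covered twice
        spans = sorted((r.query_start, r.query_end) for r in once)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


class TestIntraCalling:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.ref = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])

    def test_deletion_coordinates(self):
        # "100=10D100=" at target 1000 -> one 10-bp DEL at [1100, 1110)
        query = self.ref[1000:1100] + self.ref[1110:1210]
        r = rec(0, 200, 1000, 1210, [(100, "="), (10, "D"), (100, "=")],
                qlen=200, tlen=2000)
        (v,) = av.call_intra_alignment(r, self.ref, query)
        assert (v.vtype, v.pos, v.end) == ("DEL", 1100, 1110)
        assert v.sequence == self.ref[1100:1110]

    def test_single_snv(self):
        base = self.ref[50]
        alt = "A" if base != "A" else "C"
        query = self.ref[0:50] + alt + self.ref[51:100]
        r = rec(0, 100, 0, 100, [(50, "="), (1, "X"), (49, "=")], qlen=100, tlen=2000)
        (v,) = av.call_intra_alignment(r, self.ref, query)
        assert (v.vtype, v.pos, v.ref, v.sequence) == ("SNV", 50, base, alt)

    def test_60bp_insertion_is_sv(self):
        ins = "A" * 60
        query = self.ref[:100] + ins + self.ref[100:200]
        r = rec(0, 260, 0, 200, [(100, "="), (60, "I"), (100, "=")],
                qlen=260, tlen=2000)
        (v,) = av.call_intra_alignment(r, self.ref, query)
        assert v.vtype == "INS" and v.length == 60 and v.vclass == "SV"
        assert v.sequence == ins

    def test_short_sequence_rejected(self):
        r = rec(0, 100, 0, 100, [(100, "=")], qlen=100, tlen=10_000)
        with pytest.raises(ValueError, match="shorter"):
            av.call_intra_alignment(r, "ACGT", "ACGT" * 25)

    def test_minus_strand_query_coordinates(self):
        tseq = self.ref[:100]
        query = revcomp(tseq)
        r = rec(0, 100, 0, 100, [(40, "="), (1, "X"), (59, "=")], strand="-",
                qlen=100, tlen=2000)
        (v,) = av.call_intra_alignment(r, self.ref, query)
        # target position 40 maps to original query position 100-41
        assert (v.query_pos, v.query_end) == (59, 60)


class TestInterCalling:
    def test_target_gap_is_deletion(self):
        a = rec(0, 1000, 0, 1000, [(1000, "=")])
        b = rec(1000, 2000, 1500, 2500, [(1000, "=")])
        (v,) = av.call_inter_alignment([a, b])
        assert (v.vtype, v.pos, v.end, v.length) == ("DEL", 1000, 1500, 500)

    def test_query_gap_is_insertion(self):
        a = rec(0, 1000, 0, 1000, [(1000, "=")])
        b = rec(1200, 2200, 1000, 2000, [(1000, "=")])
        (v,) = av.call_inter_alignment([a, b])
        assert (v.vtype, v.pos, v.length) == ("INS", 1000, 200)

    def test_clean_inverted_record_is_inversion(self, ref300k):
        # oracle: reverse-complement replay reconstructs the query
        ref = ref300k.sequences["chr1"]
        a = rec(0, 1000, 0, 1000, [(1000, "=")], tname="chr1", tlen=300_000)
        m = rec(1000, 3000, 1000, 3000, [(2000, "=")], strand="-", tname="chr1",
                tlen=300_000)
        b = rec(3000, 4000, 3000, 4000, [(1000, "=")], tname="chr1", tlen=300_000)
        calls = av.call_inter_alignment([a, m, b], ref=ref)
        assert [(v.vtype, v.pos, v.end) for v in calls] == [("INV", 1000, 3000)]
        query = ref[:1000] + revcomp(ref[1000:3000]) + ref[3000:4000]
        assert av.apply_variants_to_reference(ref[:4000], calls) == query

    def test_target_overlap_of_inverted_record_is_invdup(self):
        a = rec(0, 3000, 0, 3000, [(3000, "=")])
        m = rec(3000, 7000, 1000, 5000, [(4000, "=")], strand="-")
        calls = av.call_inter_alignment([a, m])
        kinds = {v.vtype: v for v in calls}
        assert kinds["INVDUP"].length == 2000
        assert (kinds["INVDUP"].pos, kinds["INVDUP"].end) == (1000, 3000)
        assert (kinds["INV"].pos, kinds["INV"].end) == (3000, 5000)

    def test_different_queries_rejected(self):
        a = rec(0, 100, 0, 100, [(100, "=")], qname="q1")
        b = rec(100, 200, 100, 200, [(100, "=")], qname="q2")
        with pytest.raises(ValueError, match="different queries"):
            av.call_inter_alignment([a, b])


class TestExclusionFilter:
    def variants(self):
        return [
            VariantCall("DEL", "chr1", 100, 200, 100),
            VariantCall("DEL", "chr1", 300, 400, 100),
            VariantCall("INS", "chr1", 600, 600, 80),
        ]

    def test_overlap_removed_abutting_kept(self):
        excl = [IntervalAnnotation("chr1", 150, 300, "censat")]
        kept, removed = av.filter_excluded_regions(self.variants(), excl)
        assert [v.pos for v in removed] == [100]
        assert [v.pos for v in kept] == [300, 600]  # 300 abuts (end==start): kept

    def test_empty_track_keeps_all(self):
        kept, removed = av.filter_excluded_regions(self.variants(), [])
        assert len(kept) == 3 and not removed

    def test_partition_is_exhaustive_and_disjoint(self):
        excl = [IntervalAnnotation("chr1", 0, 1000, "censat")]
        kept, removed = av.filter_excluded_regions(self.variants(), excl)
        assert len(kept) + len(removed) == 3 and not kept


class TestSymmetryAndReplay:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_ins_del_symmetry_under_role_swap(self, seed):
        from csvarc import simdata as sd

        ref = sd.make_reference(seed % 1000, [80_000])
        haps, truth = sd.implant_simple_variants(
            ref, {"SNV": 10, "INS": 4, "DEL": 4}, seed=seed, ploidy=1
        )
        recs = sd.simulate_alignments(ref, haps["h1"], truth, "h1")
        qseqs = {"chr1_h1": haps["h1"]["chr1"]}
        fwd = av.discover_variants(recs, ref.sequences, qseqs)
        rev = av.discover_variants(
            [av.invert_alignment(r) for r in recs], qseqs, ref.sequences
        )
        count = lambda vs, t: sum(v.vtype == t for v in vs)
        assert count(fwd, "INS") == count(rev, "DEL")
        assert count(fwd, "DEL") == count(rev, "INS")
        assert count(fwd, "SNV") == count(rev, "SNV")

    def test_replay_reconstructs_query(self, ref300k):
        from csvarc import simdata as sd

        haps, truth = sd.implant_simple_variants(
            ref300k, {"SNV": 25, "INS": 6, "DEL": 6}, seed=77, ploidy=1
        )
        recs = sd.simulate_alignments(ref300k, haps["h1"], truth, "h1")
        calls = av.discover_variants(recs, ref300k.sequences,
                                     {"chr1_h1": haps["h1"]["chr1"]})
        rebuilt = av.apply_variants_to_reference(ref300k.sequences["chr1"], calls)
        assert rebuilt == haps["h1"]["chr1"]
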