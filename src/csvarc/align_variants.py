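"""Variant discovery from assembly-to-reference alignment records.

Intra-alignment calling walks a =/X/I/D CIGAR: X runs become SNVs, I runs
insertions and D runs deletions.  Inter-alignment calling inspects the
junctions between consecutive (query-sorted) records: a target gap with no
query gap is a deletion, a query gap an insertion, an inverted record flanked
by colinear forward records an inversion, and a target overlap between
opposite-orientation records a duplicated inversion (INVDUP — one copy in
each orientation).  Variants of 50 bp or more are structural variants.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

from intervaltree import IntervalTree

from .records import (
    SV_MIN_LENGTH,
    AlignmentRecord,
    IntervalAnnotation,
    QUERY_OPS,
    TARGET_OPS,
    VariantCall,
    cigar_matches,
    revcomp,
)

SeqSource = Union[str, dict]


def _seq_for(source: SeqSource, name: str) -> str:
    return source[name] if isinstance(source, dict) else source


# ---------------------------------------------------------------------------
# Query-overlap trimming
# ---------------------------------------------------------------------------

def _matches_lost(rec: AlignmentRecord, need_q: int, cigar_end: str) -> int:
    """'=' bases lost when trimming need_q query bases from one CIGAR end.

    Aligned (=/X) runs are split at the boundary; I/D ops are removed whole.
    """
    lost = removed = 0
    ops = rec.cigar if cigar_end == "head" else rec.cigar[::-1]
    for n, op in ops:
        if removed >= need_q:
            break
        take = min(n, need_q - removed) if op in "=X" else n
        if op == "=":
            lost += take
        if op in QUERY_OPS:
            removed += take
    return lost


def _trim(rec: AlignmentRecord, need_q: int, query_side: str) -> Optional[AlignmentRecord]:
    """Trim need_q query bases off one query side of a record.

    Aligned (=/X) runs are split at the boundary; I/D ops are removed whole,
    and a record never starts or ends in I or D afterwards.  For a
    minus-strand record the query_start side corresponds to the CIGAR tail
    (the CIGAR is in target order).  Returns None if nothing remains.
    """
    cigar_end = "head" if (query_side == "query_start") == (rec.strand == "+") else "tail"
    ops = list(rec.cigar)
    removed_q = removed_t = 0
    while ops and removed_q < need_q:
        n, op = ops.pop(0 if cigar_end == "head" else -1)
        if op in "=X" and n > need_q - removed_q:
            keep = n - (need_q - removed_q)
            removed_q += n - keep
            removed_t += n - keep
            ops.insert(0 if cigar_end == "head" else len(ops), (keep, op))
            break
        if op in QUERY_OPS:
            removed_q += n
        if op in TARGET_OPS:
            removed_t += n
    # never leave a record starting/ending in I or D
    while ops and ops[0 if cigar_end == "head" else -1][1] in "ID":
        n, op = ops.pop(0 if cigar_end == "head" else -1)
        if op in QUERY_OPS:
            removed_q += n
        if op in TARGET_OPS:
            removed_t += n
    if not ops:
        return None
    if cigar_end == "head":
        rec.target_start += removed_t
    else:
        rec.target_end -= removed_t
    if query_side == "query_start":
        rec.query_start += removed_q
    else:
        rec.query_end -= removed_q
    rec.cigar = ops
    if rec.query_start >= rec.query_end or rec.target_start >= rec.target_end:
        return None
    return rec.validate()


def trim_query_overlaps(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Resolve query-space overlaps between records of one query.

    Each pairwise overlap is removed from whichever record loses fewer '='
    bases (ties: trim the record with the larger target coordinate); trimming
    removes whole CIGAR ops from record ends.  Duplicate and emptied records
    are dropped.  Idempotent.
    """
    names = {r.query_name for r in records}
    if len(names) > 1:
        raise ValueError(f"records span multiple queries: {sorted(names)}")
    recs: list[AlignmentRecord] = []
    seen = set()
    for r in records:
        key = (r.query_start, r.query_end, r.strand, r.target_name,
               r.target_start, r.target_end, tuple(r.cigar))
        if key not in seen and r.query_end > r.query_start:
            seen.add(key)
            recs.append(r)
    while True:
        recs.sort(key=lambda r: (r.query_start, r.query_end))
        clash = None
        for a, b in zip(recs, recs[1:]):
            if a.query_end > b.query_start:
                clash = (a, b)
                break
        if clash is None:
            return recs
        a, b = clash
        overlap = a.query_end - b.query_start
        lost_a = _matches_lost(a, overlap, "head" if a.strand == "-" else "tail")
        lost_b = _matches_lost(b, overlap, "tail" if b.strand == "-" else "head")
        if lost_a < lost_b or (lost_a == lost_b and a.target_start >= b.target_start):
            victim, side = a, "query_end"
        else:
            victim, side = b, "query_start"
        trimmed = _trim(victim, overlap, side)
        recs = [r for r in recs if r is not victim]
        if trimmed is not None:
            recs.append(trimmed)


# ---------------------------------------------------------------------------
# Intra-alignment variant calling
# ---------------------------------------------------------------------------

def _query_interval(rec: AlignmentRecord, qi: int, n: int) -> tuple[int, int]:
    """Original-strand query interval of alignment-order positions [qi, qi+n)."""
    if rec.strand == "+":
        return rec.query_start + qi, rec.query_start + qi + n
    return rec.query_end - qi - n, rec.query_end - qi


def call_intra_alignment(
    record: AlignmentRecord, ref: SeqSource, query: SeqSource
) -> list[VariantCall]:
    """Call SNVs, insertions and deletions inside one alignment record."""
    tseq = _seq_for(ref, record.target_name)
    qfull = _seq_for(query, record.query_name)
    if len(tseq) < record.target_end or len(qfull) < record.query_end:
        raise ValueError("sequence shorter than the alignment record claims")
    qa = qfull[record.query_start : record.query_end]
    if record.strand == "-":
        qa = revcomp(qa)
    out: list[VariantCall] = []
    t, qi = record.target_start, 0
    for n, op in record.cigar:
        if op == "=":
            t += n
            qi += n
        elif op == "X":
            for k in range(n):
                qs, qe = _query_interval(record, qi + k, 1)
                out.append(
                    VariantCall("SNV", record.target_name, t + k, t + k + 1, 1,
                                sequence=qa[qi + k], ref=tseq[t + k],
                                query_name=record.query_name, query_pos=qs,
                                query_end=qe, source="intra")
                )
            t += n
            qi += n
        elif op == "I":
            qs, qe = _query_interval(record, qi, n)
            out.append(
                VariantCall("INS", record.target_name, t, t, n,
                            sequence=qa[qi : qi + n], query_name=record.query_name,
                            query_pos=qs, query_end=qe, source="intra")
            )
            qi += n
        elif op == "D":
            qs, qe = _query_interval(record, qi, 0)
            out.append(
                VariantCall("DEL", record.target_name, t, t + n, n,
                            sequence=tseq[t : t + n], query_name=record.query_name,
                            query_pos=qs, query_end=qe, source="intra")
            )
            t += n
        else:
            raise ValueError(f"unexpected CIGAR op {op!r}")
    return out


# ---------------------------------------------------------------------------
# Inter-alignment variant calling
# ---------------------------------------------------------------------------

def _map_t_to_q(rec: AlignmentRecord, t: int) -> int:
    """Approximate original-strand query position of a target position
    (exact for gap-free records)."""
    off = min(max(t - rec.target_start, 0), rec.target_span)
    frac = off / rec.target_span if rec.target_span else 0
    qoff = round(frac * rec.query_span)
    if rec.strand == "+":
        return rec.query_start + qoff
    return rec.query_end - qoff


def pair_variants(
    a: AlignmentRecord,
    b: AlignmentRecord,
    ref: Optional[SeqSource] = None,
    query: Optional[SeqSource] = None,
) -> list[VariantCall]:
    """Variants implied by the junction between two query-consecutive records."""
    if a.query_name != b.query_name:
        raise ValueError("records on different queries")
    tseq = _seq_for(ref, a.target_name) if ref is not None else None
    qseq = _seq_for(query, a.query_name) if query is not None else None
    out: list[VariantCall] = []

    def del_call(lo: int, hi: int):
        out.append(
            VariantCall("DEL", a.target_name, lo, hi, hi - lo,
                        sequence=tseq[lo:hi] if tseq else "",
                        query_name=a.query_name, query_pos=a.query_end,
                        query_end=a.query_end, source="inter")
        )

    if a.strand == b.strand:
        if a.strand == "+":
            tgap = b.target_start - a.target_end
            if tgap > 0:
                del_call(a.target_end, b.target_start)
            elif tgap < 0:
                lo, hi = b.target_start, min(a.target_end, b.target_end)
                if hi > lo:
                    out.append(
                        VariantCall("DUP", a.target_name, lo, hi, hi - lo,
                                    sequence=tseq[lo:hi] if tseq else "",
                                    query_name=a.query_name, source="inter")
                    )
        else:
            tgap = a.target_start - b.target_end
            if tgap > 0:
                del_call(b.target_end, a.target_start)
    else:
        lo = max(a.target_start, b.target_start)
        hi = min(a.target_end, b.target_end)
        if hi > lo:  # duplicated inversion: one copy in each orientation
            m = a if a.strand == "-" else b
            out.append(
                VariantCall("INVDUP", a.target_name, lo, hi, hi - lo,
                            sequence=tseq[lo:hi] if tseq else "",
                            query_name=a.query_name,
                            query_pos=min(_map_t_to_q(m, lo), _map_t_to_q(m, hi)),
                            query_end=max(_map_t_to_q(m, lo), _map_t_to_q(m, hi)),
                            source="inter")
            )
        else:
            gap_lo = min(a.target_end, b.target_end)
            gap_hi = max(a.target_start, b.target_start)
            if gap_hi > gap_lo:
                del_call(gap_lo, gap_hi)
    qgap = b.query_start - a.query_end
    if qgap > 0:
        anchor = a.target_end if a.strand == "+" else a.target_start
        out.append(
            VariantCall("INS", a.target_name, anchor, anchor, qgap,
                        sequence=qseq[a.query_end : b.query_start] if qseq else "",
                        query_name=a.query_name, query_pos=a.query_end,
                        query_end=b.query_start, source="inter")
        )
    return out


def call_inter_alignment(
    records: Sequence[AlignmentRecord],
    ref: Optional[SeqSource] = None,
    query: Optional[SeqSource] = None,
) -> list[VariantCall]:
    """Variants between consecutive records of one query.

    Besides the pairwise junction variants, each minus-strand record flanked
    by forward records yields an inversion of the part of its target span not
    duplicated in a neighbour.
    """
    if not records:
        return []
    if len({r.query_name for r in records}) > 1:
        raise ValueError("records on different queries")
    recs = sorted(records, key=lambda r: (r.query_start, r.query_end))
    out: list[VariantCall] = []
    for a, b in zip(recs, recs[1:]):
        out.extend(pair_variants(a, b, ref, query))
    tseq = _seq_for(ref, recs[0].target_name) if ref is not None else None
    for idx, m in enumerate(recs):
        if m.strand != "-":
            continue
        left = recs[idx - 1] if idx > 0 else None
        right = recs[idx + 1] if idx + 1 < len(recs) else None
        ov_left = ov_right = 0
        if left is not None and left.strand == "+":
            ov_left = min(max(0, left.target_end - m.target_start), m.target_span)
        if right is not None and right.strand == "+":
            ov_right = min(max(0, m.target_end - right.target_start), m.target_span)
        lo = m.target_start + ov_left
        hi = m.target_end - ov_right
        if hi > lo:
            out.append(
                VariantCall("INV", m.target_name, lo, hi, hi - lo,
                            sequence=tseq[lo:hi] if tseq else "",
                            query_name=m.query_name,
                            query_pos=min(_map_t_to_q(m, lo), _map_t_to_q(m, hi)),
                            query_end=max(_map_t_to_q(m, lo), _map_t_to_q(m, hi)),
                            source="inter")
            )
    out.sort(key=lambda v: (v.pos, v.end))
    return out


# ---------------------------------------------------------------------------
# Region exclusion
# ---------------------------------------------------------------------------

def filter_excluded_regions(
    variants: Iterable[VariantCall],
    exclusions: Iterable[IntervalAnnotation],
    mode: str = "any_overlap",
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition variants into (kept, removed) by >= 1 base overlap with any
    exclusion interval.  Point-like insertions count as the single base at
    their anchor position.  Callers pre-filter the track (e.g. dropping
    monomeric rows from a CenSat-style track)."""
    if mode != "any_overlap":
        raise ValueError(f"unknown mode {mode!r}")
    trees: dict[str, IntervalTree] = {}
    for a in exclusions:
        trees.setdefault(a.chrom, IntervalTree()).addi(a.start, a.end)
    kept, removed = [], []
    for v in variants:
        lo, hi = v.pos, max(v.end, v.pos + 1)
        tree = trees.get(v.chrom)
        (removed if tree is not None and tree.overlap(lo, hi) else kept).append(v)
    return kept, removed


# ---------------------------------------------------------------------------
# Replay and role inversion
# ---------------------------------------------------------------------------

def apply_variants_to_reference(refseq: str, variants: Sequence[VariantCall]) -> str:
    """Replay called variants on the reference, reconstructing the query.

    Adjacent INV/INVDUP calls are grouped into one inverted run: the union
    span is reverse-complemented and INVDUP flanks additionally keep their
    direct copy on the outer side (one copy in each orientation).
    """
    vs = sorted(variants, key=lambda v: (v.pos, v.end))
    for u, w in zip(vs, vs[1:]):
        if max(u.end, u.pos) > w.pos:
            raise ValueError(f"overlapping variants at {u.pos} and {w.pos}")
    out: list[str] = []
    t = 0
    i = 0
    while i < len(vs):
        v = vs[i]
        out.append(refseq[t : v.pos])
        if v.vtype in ("INV", "INVDUP"):
            j = i
            while (
                j + 1 < len(vs)
                and vs[j + 1].vtype in ("INV", "INVDUP")
                and vs[j + 1].pos == vs[j].end
            ):
                j += 1
            run = vs[i : j + 1]
            if run[0].vtype == "INVDUP":
                out.append(refseq[run[0].pos : run[0].end])
            out.append(revcomp(refseq[run[0].pos : run[-1].end]))
            if len(run) > 1 and run[-1].vtype == "INVDUP":
                out.append(refseq[run[-1].pos : run[-1].end])
            t = run[-1].end
            i = j + 1
            continue
        if v.vtype == "SNV":
            out.append(v.sequence)
            t = v.pos + 1
        elif v.vtype == "INS":
            out.append(v.sequence)
            t = v.pos
        elif v.vtype == "DEL":
            t = v.end
        elif v.vtype == "DUP":
            out.append(refseq[v.pos : v.end] * 2)
            t = v.end
        else:
            raise ValueError(f"cannot replay variant type {v.vtype}")
        i += 1
    out.append(refseq[t:])
    return "".join(out)


def invert_alignment(rec: AlignmentRecord) -> AlignmentRecord:
    """Swap query and target roles of a forward-strand record (I <-> D)."""
    if rec.strand != "+":
        raise ValueError("role inversion is defined for forward-strand records")
    swap = {"I": "D", "D": "I"}
    return AlignmentRecord(
        query_name=rec.target_name, query_start=rec.target_start,
        query_end=rec.target_end, query_len=rec.target_len, strand="+",
        target_name=rec.query_name, target_start=rec.query_start,
        target_end=rec.query_end, target_len=rec.query_len,
        cigar=[(n, swap.get(op, op)) for n, op in rec.cigar], mapq=rec.mapq,
    ).validate()


def discover_variants(
    records: Sequence[AlignmentRecord],
    ref: SeqSource,
    query: SeqSource,
    exclusions: Optional[Iterable[IntervalAnnotation]] = None,
) -> list[VariantCall]:
    """Trim, call intra- and inter-alignment variants and apply exclusions."""
    by_query: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_query.setdefault(r.query_name, []).append(r)
    out: list[VariantCall] = []
    for recs in by_query.values():
        trimmed = trim_query_overlaps(recs)
        for r in trimmed:
            out.extend(call_intra_alignment(r, ref, query))
        out.extend(call_inter_alignment(trimmed, ref, query))
    if exclusions is not None:
        out, _ = filter_excluded_regions(out, exclusions)
    out.sort(key=lambda v: (v.chrom, v.pos, v.end))
    return out
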