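"""Haplotype quality evaluation.

Implements the Phred-scaled quality measures used to evaluate reconstructed
or assembled haplotypes:

* windowed variant QV over a diploid consensus pair,
  ``-10 * log10(bp_changes / (2 * window_size))`` per 1-Mb reference window,
  with a count of erroneous variants longer than 20 bp;
* k-mer QV and completeness against an error-free k-mer set
  (``error_rate = 1 - (1 - asm_only/total)^(1/k)``, canonical k-mers);
* haplotype availability QV: the highest Phred-scaled similarity between a
  haplotype and any member of a reference panel;
* parental support: child bases covered by '=' CIGAR ops from a parent
  assembly, over contigs above a minimum length;
* telomere-to-telomere status classification of an assembled chromosome.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence, Union

import edlib
import numpy as np

from .records import (
    AlignmentRecord,
    AvailabilityQV,
    IntervalAnnotation,
    KmerQVResult,
    WindowQV,
)

QV_CAP = 99.0

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i
    _BASE_CODE[ord(b.lower())] = i


def phred(rate: float, cap: float = QV_CAP) -> float:
    if rate <= 0:
        return cap
    return min(cap, -10.0 * math.log10(rate))


# ---------------------------------------------------------------------------
# Windowed variant QV
# ---------------------------------------------------------------------------

def window_variant_qv(
    error_positions: Sequence[tuple[int, int, int, int]],
    window_size: int = 1_000_000,
    ref_length: Optional[int] = None,
    chrom: str = "",
    large_error_bp: int = 20,
    cap: float = QV_CAP,
    mode: str = "bases",
) -> tuple[list[WindowQV], float]:
    """Per-window QV along one reference haplotype plus the median.

    ``error_positions`` lists erroneous variant positions as
    (position, bases changed in haplotype 1, bases changed in haplotype 2,
    variant length).  ``mode='bases'`` sums changed bases over both consensus
    haplotypes; ``mode='variants'`` counts conflicting variants instead.
    Variants longer than ``large_error_bp`` are tallied separately.
    """
    if mode not in ("bases", "variants"):
        raise ValueError(f"unknown mode {mode!r}")
    if any(b1 < 0 or b2 < 0 or ln < 0 for _, b1, b2, ln in error_positions):
        raise ValueError("negative change counts")
    if ref_length is None:
        ref_length = max((p for p, *_ in error_positions), default=0) + 1
    n_windows = max(1, math.ceil(ref_length / window_size))
    bp = np.zeros(n_windows, dtype=np.int64)
    large = np.zeros(n_windows, dtype=np.int64)
    for pos, b1, b2, length in error_positions:
        w = pos // window_size
        if w >= n_windows:
            raise ValueError(f"position {pos} beyond reference length {ref_length}")
        bp[w] += (b1 + b2) if mode == "bases" else 1
        if length > large_error_bp:
            large[w] += 1
    windows = []
    for w in range(n_windows):
        start = w * window_size
        end = min(start + window_size, ref_length)
        changes = int(bp[w])
        if changes > 0:
            qv = -10.0 * math.log10(changes / (2.0 * window_size))
            capped = False
        else:
            qv, capped = cap, True
        windows.append(
            WindowQV(chrom=chrom, start=start, end=end, bp_changes=changes,
                     qv=qv, n_large_errors=int(large[w]), capped=capped)
        )
    median = float(np.median([w.qv for w in windows]))
    return windows, median


# ---------------------------------------------------------------------------
# k-mer QV and completeness
# ---------------------------------------------------------------------------

def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer codes (2 bits/base) at every position of one sequence."""
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(arr > 3):
        raise ValueError("sequence contains non-ACGT characters")
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    comp = (3 - arr).astype(np.uint64)
    a64 = arr.astype(np.uint64)
    for i in range(k):
        fwd = (fwd << np.uint64(2)) | a64[i : i + n]
        # reverse complement read right-to-left
        rev = (rev << np.uint64(2)) | comp[k - 1 - i : k - 1 - i + n]
    return np.minimum(fwd, rev)


def _sorted_unique(codes: np.ndarray) -> np.ndarray:
    s = np.sort(codes)
    if len(s) == 0:
        return s
    return s[np.concatenate(([True], s[1:] != s[:-1]))]


def _member_count(sorted_set: np.ndarray, sorted_queries: np.ndarray) -> int:
    """How many of the sorted queries occur in the sorted set."""
    if len(sorted_set) == 0 or len(sorted_queries) == 0:
        return 0
    idx = np.searchsorted(sorted_set, sorted_queries)
    idx[idx == len(sorted_set)] = 0
    return int((sorted_set[idx] == sorted_queries).sum())


def kmer_set(sequences: Union[str, Mapping[str, str]], k: int = 21) -> np.ndarray:
    """Sorted unique canonical k-mer codes of one or more sequences."""
    seqs = [sequences] if isinstance(sequences, str) else list(sequences.values())
    parts = [_kmer_codes(s, k) for s in seqs if len(s) >= k]
    if not parts:
        raise ValueError(f"no sequence of length >= k={k}")
    return _sorted_unique(np.concatenate(parts))


def kmer_qv(
    assembly: Union[str, Mapping[str, str]],
    truth_kmers: Union[np.ndarray, str, Mapping[str, str]],
    k: int = 21,
    cap: float = QV_CAP,
) -> KmerQVResult:
    """Merqury-style k-mer QV and completeness of an assembly.

    ``truth_kmers`` is the canonical k-mer set of an error-free source (or
    sequences to derive it from).  Every k-mer position of the assembly is
    checked against the set; the per-base error rate is
    ``1 - (1 - asm_only/total)^(1/k)``, the QV its Phred scale, and
    completeness the fraction of truth k-mers present in the assembly.
    """
    if k % 2 == 0 or k < 3:
        raise ValueError("k must be odd and >= 3")
    seqs = [assembly] if isinstance(assembly, str) else list(assembly.values())
    if not seqs or all(len(s) == 0 for s in seqs):
        raise ValueError("empty assembly")
    if any(len(s) < k for s in seqs):
        raise ValueError(f"assembly sequence shorter than k={k}")
    if not isinstance(truth_kmers, np.ndarray):
        truth_kmers = kmer_set(truth_kmers, k)
    total = 0
    asm_only = 0
    asm_distinct = []
    for s in seqs:
        codes = np.sort(_kmer_codes(s, k))
        total += len(codes)
        asm_only += len(codes) - _member_count(truth_kmers, codes)
        asm_distinct.append(_sorted_unique(codes))
    distinct = _sorted_unique(np.concatenate(asm_distinct))
    completeness = _member_count(distinct, truth_kmers) / len(truth_kmers)
    if asm_only == 0:
        return KmerQVResult(k, total, 0, 0.0, cap, completeness, capped=True)
    error_rate = 1.0 - (1.0 - asm_only / total) ** (1.0 / k)
    return KmerQVResult(k, total, asm_only, error_rate, phred(error_rate, cap),
                        completeness)


# ---------------------------------------------------------------------------
# Haplotype availability QV
# ---------------------------------------------------------------------------

def availability_qv(
    target: str,
    panel: Mapping[str, str],
    target_id: str = "target",
    cap: float = QV_CAP,
) -> AvailabilityQV:
    """Highest Phred-scaled divergence-based QV of a haplotype vs a panel.

    Divergence to a panel member is the global-alignment edit fraction
    (edits / alignment columns); the reported QV is the maximum over members.
    """
    if not panel:
        raise ValueError("empty reference panel")
    best: Optional[AvailabilityQV] = None
    for name in sorted(panel):
        seq = panel[name]
        res = edlib.align(target, seq, task="path")
        edits = res["editDistance"]
        columns = sum(
            int(n) for n, _ in _split_edlib_cigar(res["cigar"])
        ) if res["cigar"] else max(len(target), len(seq))
        divergence = edits / columns if columns else 0.0
        qv = phred(divergence, cap)
        cand = AvailabilityQV(target_id, name, divergence, qv, capped=divergence == 0.0)
        if best is None or cand.qv > best.qv:
            best = cand
    return best


def _split_edlib_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


# ---------------------------------------------------------------------------
# Parental support
# ---------------------------------------------------------------------------

def parental_support(
    child_records: Sequence[AlignmentRecord],
    min_contig: int = 100_000,
) -> tuple[dict[str, float], float]:
    """Fraction of child-contig bases supported by a parent assembly.

    ``child_records`` align parent contigs (queries) onto child contigs
    (targets); a child base is supported when covered by an '=' op from at
    least one parent record.  Contigs below ``min_contig`` are excluded.
    Returns (per-contig fractions, overall supported fraction).
    """
    lengths: dict[str, int] = {}
    for r in child_records:
        lengths[r.target_name] = r.target_len
    masks = {
        c: np.zeros(L, dtype=bool) for c, L in lengths.items() if L >= min_contig
    }
    for r in child_records:
        mask = masks.get(r.target_name)
        if mask is None:
            continue
        t = r.target_start
        for n, op in r.cigar:
            if op == "=":
                mask[t : t + n] = True
            if op in "=XD":
                t += n
    per_contig = {c: float(m.mean()) for c, m in masks.items()}
    total = sum(len(m) for m in masks.values())
    supported = sum(int(m.sum()) for m in masks.values())
    overall = supported / total if total else 0.0
    return per_contig, overall


# ---------------------------------------------------------------------------
# T2T status
# ---------------------------------------------------------------------------

def classify_t2t(
    coverage: Sequence[IntervalAnnotation],
    telomeres: Sequence[IntervalAnnotation],
    gap_positions: Iterable[int],
    chrom_length: int,
    end_window: int = 10_000,
    min_telomere: int = 1_000,
) -> str:
    """Classify one chromosome of one haplotype.

    'T2T contig': a single gapless sequence spans the chromosome with
    telomere annotation at both ends; 'T2T scaffold': the same but the
    spanning sequence contains one or more N-gaps; 'missing': no aligned
    sequence; otherwise 'not T2T'.  ``coverage`` intervals carry the
    contig/scaffold name in their label.
    """
    if not coverage:
        return "missing"
    names = {c.label for c in coverage}
    start = min(c.start for c in coverage)
    end = max(c.end for c in coverage)
    if len(names) > 1 or start > 0 or end < chrom_length:
        return "not T2T"

    def telomere_bases(lo: int, hi: int) -> int:
        return sum(
            max(0, min(t.end, hi) - max(t.start, lo)) for t in telomeres
        )

    if (
        telomere_bases(0, end_window) < min_telomere
        or telomere_bases(chrom_length - end_window, chrom_length) < min_telomere
    ):
        return "not T2T"
    gaps = [g for g in gap_positions if 0 <= g < chrom_length]
    return "T2T scaffold" if gaps else "T2T contig"
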