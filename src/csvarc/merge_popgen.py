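"""Non-redundant population merging, allele frequencies, discovery curves.

Two variants merge when they share a type and satisfy 50% reciprocal overlap
(interval classes) and 80% sequence identity (sequence-bearing classes);
insertions, point-like on the reference, use a breakpoint-distance window in
place of reciprocal overlap.  Merging is greedy and seed-based: variants are
processed by descending carrier count then leftmost coordinate, and each
unassigned variant joins the first qualifying seed, which makes the result
deterministic and independent of input file order.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np

from .records import MergedVariant, VariantCall

DEFAULT_RO = 0.5
DEFAULT_SEQ_MATCH = 0.8
INS_DIST_FLOOR = 50


def sequence_identity(a: str, b: str) -> float:
    """Levenshtein-normalised identity: 1 - d(a, b) / max(|a|, |b|)."""
    if not a or not b:
        return 1.0 if a == b else 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def reciprocal_overlap(a: VariantCall, b: VariantCall) -> float:
    ov = min(a.end, b.end) - max(a.pos, b.pos)
    if ov <= 0:
        return 0.0
    return min(ov / (a.end - a.pos), ov / (b.end - b.pos))


def merge_compatible(
    a: VariantCall,
    b: VariantCall,
    ro: float = DEFAULT_RO,
    seq_match: float = DEFAULT_SEQ_MATCH,
) -> bool:
    """The pairwise merge predicate (symmetric)."""
    if a.vtype != b.vtype or a.chrom != b.chrom:
        return False
    if a.vtype == "SNV":
        return a.pos == b.pos and a.sequence == b.sequence
    if a.vtype == "INS":
        window = max(INS_DIST_FLOOR, 0.5 * max(a.length, b.length))
        if abs(a.pos - b.pos) > window:
            return False
    else:
        if reciprocal_overlap(a, b) < ro:
            return False
    if a.sequence and b.sequence:
        lo, hi = sorted((len(a.sequence), len(b.sequence)))
        if lo / hi < seq_match:  # size-ratio prefilter
            return False
        return sequence_identity(a.sequence, b.sequence) >= seq_match
    return True


def _merge_items(
    items: Sequence[tuple[VariantCall, frozenset]],
    ro: float,
    seq_match: float,
) -> list[MergedVariant]:
    order = sorted(
        range(len(items)),
        key=lambda i: (
            -len(items[i][1]),
            items[i][0].chrom,
            items[i][0].pos,
            items[i][0].end,
            items[i][0].vtype,
            items[i][0].id,
            items[i][0].sequence,
            tuple(sorted(items[i][1])),
        ),
    )
    merged: list[MergedVariant] = []
    for idx in order:
        variant, carriers = items[idx]
        for m in merged:
            if merge_compatible(m.representative, variant, ro, seq_match):
                m.carriers = m.carriers | carriers
                m.members.append(variant)
                break
        else:
            merged.append(
                MergedVariant(representative=variant, carriers=frozenset(carriers),
                              members=[variant])
            )
    for m in merged:
        for h in m.carriers:
            m.genotypes[h] = "present"
    merged.sort(key=lambda m: (m.representative.chrom, m.representative.pos,
                               m.representative.end, m.representative.vtype))
    return merged


def merge_nonredundant(
    callsets: Mapping[str, Sequence[VariantCall]],
    ro: float = DEFAULT_RO,
    seq_match: float = DEFAULT_SEQ_MATCH,
) -> list[MergedVariant]:
    """Merge per-haplotype callsets into a non-redundant population set."""
    items = [
        (v, frozenset([hap]))
        for hap, variants in callsets.items()
        for v in variants
    ]
    return _merge_items(items, ro, seq_match)


def remerge(
    merged: Sequence[MergedVariant],
    ro: float = DEFAULT_RO,
    seq_match: float = DEFAULT_SEQ_MATCH,
) -> list[MergedVariant]:
    """Merge an already-merged set with itself (idempotence surface)."""
    items = [(m.representative, m.carriers) for m in merged]
    return _merge_items(items, ro, seq_match)


def compute_allele_frequency(
    merged: Sequence[MergedVariant],
    n_haplotypes: int,
    missing_marks: Optional[Mapping[str, Iterable[str]]] = None,
    exclude_haps: Iterable[str] = (),
) -> list[MergedVariant]:
    """AF = carriers / (haplotypes - missing).

    ``missing_marks`` maps a merged variant's representative id to the
    haplotypes marked '.' (misassembled there); those haplotypes are excluded
    from the denominator.  ``exclude_haps`` removes haplotypes (e.g. trio
    children) from both numerator and denominator.  A variant with no
    genotyped haplotype left gets an undefined AF flag.
    """
    missing_marks = missing_marks or {}
    excl = set(exclude_haps)
    for m in merged:
        missing = set(missing_marks.get(m.representative.id, ())) - excl
        for h in missing:
            m.genotypes[h] = "missing"
        carriers = {h for h in m.carriers if h not in excl and h not in missing}
        denom = n_haplotypes - len(excl) - len(missing)
        if denom <= 0:
            m.allele_frequency = None
            m.af_undefined = True
        else:
            m.allele_frequency = len(carriers) / denom
            m.af_undefined = False
    return list(merged)


def discovery_curve(
    merged: Sequence[MergedVariant],
    haplotype_order: Optional[Sequence[str]] = None,
    permutation_seeds: Optional[Sequence[int]] = None,
    haplotypes: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Cumulative novel merged variants as haplotypes are added.

    Position i counts variants whose first carrier (in the given order) is
    haplotype i, cumulatively summed; with ``permutation_seeds`` the mean
    curve over seeded shuffles is returned.  The final value always equals
    the total merged count of variants carried by the ordered haplotypes.
    """
    if haplotypes is None:
        haplotypes = sorted({h for m in merged for h in m.carriers})
    if permutation_seeds is not None:
        curves = []
        for seed in permutation_seeds:
            rng = np.random.default_rng(seed)
            order = list(haplotypes)
            rng.shuffle(order)
            curves.append(discovery_curve(merged, haplotype_order=order))
        return np.mean(curves, axis=0)
    order = list(haplotype_order) if haplotype_order is not None else list(haplotypes)
    rank = {h: i for i, h in enumerate(order)}
    counts = np.zeros(len(order), dtype=float)
    for m in merged:
        ranks = [rank[h] for h in m.carriers if h in rank]
        if ranks:
            counts[min(ranks)] += 1
    return np.cumsum(counts)


def annotate_support(
    lead: Sequence[MergedVariant],
    others: Mapping[str, Sequence[VariantCall]],
    ro: float = DEFAULT_RO,
    seq_match: float = DEFAULT_SEQ_MATCH,
) -> float:
    """Per-caller support flags on the lead callset.

    A lead variant is supported by a caller when any of that caller's variants
    qualifies under the merge predicate.  Returns the fraction of lead
    variants supported by at least one other caller.
    """
    supported_any = 0
    for m in lead:
        any_hit = False
        for caller, variants in others.items():
            hit = any(
                merge_compatible(m.representative, v, ro, seq_match) for v in variants
            )
            m.support[caller] = hit
            any_hit |= hit
        supported_any += any_hit
    return supported_any / len(lead) if lead else 0.0
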