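"""Centromere analytics: HOR array lengths, CDR detection, di-CDR, MEI placement.

A centromere dip region (CDR) is a run of 5-kb methylation bins strictly
below the median CpG methylation of the alpha-satellite region, merged and
kept when longer than 50 kb; it proxies the kinetochore position.  Array
lengths span the minimum to maximum coordinate of live ('L') higher-order
repeat rows; two CDRs more than 80 kb apart flag a candidate di-kinetochore.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .records import CDRInterval, HORRow, IntervalAnnotation, MethylTrack


def hor_array_lengths(
    rows: Sequence[HORRow], join_distance: int = 50_000
) -> list[tuple[IntervalAnnotation, int]]:
    """Live HOR rows grouped into arrays by adjacency; per array the interval
    spanning the minimum and maximum coordinate and its length.  Divergent
    rows are ignored; rows separated by more than ``join_distance`` start a
    new array."""
    live = sorted(
        (r for r in rows if r.status == "live"), key=lambda r: r.interval.start
    )
    if not live:
        return []
    arrays: list[list[HORRow]] = [[live[0]]]
    for row in live[1:]:
        if row.interval.start - arrays[-1][-1].interval.end <= join_distance:
            arrays[-1].append(row)
        else:
            arrays.append([row])
    out = []
    for grp in arrays:
        start = min(r.interval.start for r in grp)
        end = max(r.interval.end for r in grp)
        iv = IntervalAnnotation(grp[0].interval.chrom, start, end, "hor_array")
        out.append((iv, end - start))
    return out


def detect_cdrs(
    track: MethylTrack,
    alphasat: Sequence[IntervalAnnotation],
    min_len: int = 50_000,
    min_overlap_frac: float = 0.5,
) -> list[CDRInterval]:
    """Hypomethylated dip regions within the alpha-satellite annotation.

    The median methylation is computed over bins overlapping alpha-satellite
    by at least ``min_overlap_frac`` of the bin; bins strictly below that
    median are selected, consecutive selected bins merged, and merged runs
    longer than ``min_len`` reported with their mean methylation.
    """
    regions = [(a.start, a.end) for a in alphasat if a.chrom == track.chrom]
    in_region = []
    for start, end, frac in track.bins:
        ov = sum(max(0, min(end, e) - max(start, s)) for s, e in regions)
        if ov >= min_overlap_frac * (end - start):
            in_region.append((start, end, frac))
    if len(in_region) < 3:
        raise ValueError(
            f"only {len(in_region)} bins overlap alpha-satellite: median is meaningless"
        )
    median = float(np.median([b[2] for b in in_region]))
    selected = [b for b in in_region if b[2] < median]
    cdrs: list[CDRInterval] = []
    run: list[tuple[int, int, float]] = []

    def flush():
        if not run:
            return
        length = run[-1][1] - run[0][0]
        if length > min_len:
            cdrs.append(
                CDRInterval(
                    chrom=track.chrom, start=run[0][0], end=run[-1][1],
                    mean_methylation=float(np.mean([b[2] for b in run])),
                    n_bins=len(run), merged_from=len(run),
                )
            )

    for b in selected:
        if run and b[0] == run[-1][1]:
            run.append(b)
        else:
            flush()
            run = [b]
    flush()
    return cdrs


def classify_dicdr(
    cdrs: Sequence[CDRInterval], min_separation: int = 80_000
) -> tuple[int, bool]:
    """(CDR count, di-CDR flag): true when at least two CDRs lie more than
    ``min_separation`` apart, measured edge to edge."""
    ordered = sorted(cdrs, key=lambda c: c.start)
    is_multi = any(
        b.start - a.end > min_separation
        for i, a in enumerate(ordered)
        for b in ordered[i + 1 :]
    )
    return len(ordered), is_multi


@dataclass
class MEIPlacement:
    name: str
    position: int
    placement: str  # inside_cdr / between_cdrs / outside_cdr
    distance_to_edge: int
    in_array: bool


def place_meis(
    mei_positions: Sequence[IntervalAnnotation],
    cdrs: Sequence[CDRInterval],
    array_interval: tuple[int, int],
) -> list[MEIPlacement]:
    """Place each mobile element insertion relative to the CDRs of an array.

    inside_cdr: overlaps a CDR; between_cdrs: at least one CDR on each side;
    otherwise outside_cdr.  The periphery distance is the distance from the
    element midpoint to the nearest array edge.  Elements outside the array
    are flagged, not rejected.
    """
    a_start, a_end = array_interval
    out = []
    for mei in mei_positions:
        mid = (mei.start + mei.end) // 2
        in_array = a_start <= mid < a_end
        if any(c.start < mei.end and mei.start < c.end for c in cdrs):
            placement = "inside_cdr"
        elif any(c.end <= mei.start for c in cdrs) and any(
            c.start >= mei.end for c in cdrs
        ):
            placement = "between_cdrs"
        else:
            placement = "outside_cdr"
        dist = min(abs(mid - a_start), abs(a_end - mid))
        out.append(
            MEIPlacement(mei.name or mei.label, mid, placement, int(dist), in_array)
        )
    return out
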