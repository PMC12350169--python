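"""Seeded generator of references, diploid haplotypes and exact alignments.

The generator implants events on a reference and *realizes* each haplotype
from the ledger: the haplotype sequence and its exact split alignments (CIGAR
over =/X/I/D) are derived from the same event walk, so the ledger, sequence
and alignment records are consistent by construction.  Inverted segments are
emitted as separate minus-strand records; the record set tiles the query
without overlap and concatenating the per-record query segments reconstructs
the haplotype.

Complex-SV templates are token signatures over {DEL, INV, INVDUP} with one
contiguous inverted run: e.g. ``DEL-INV-DEL`` deletes both flanking segments
and inverts the middle one; an INVDUP flank keeps its direct copy and also
appears inside the inverted copy (one copy in each orientation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import (
    AlignmentRecord,
    CsvEvent,
    CsvTemplate,
    IntervalAnnotation,
    MethylTrack,
    ReferenceGenome,
    TruthSet,
    VariantCall,
    revcomp,
)

BASES = np.array(list("ACGT"))

DEFAULT_SIZE_RANGES = {"SNV": (1, 1), "INS": (50, 500), "DEL": (50, 500)}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

ALPHA_MONOMER_LEN = 171  # canonical alpha-satellite monomer size


def make_reference(
    seed: int,
    chrom_lengths: Sequence[int],
    centromere_spec: Optional[Mapping[str, tuple[int, int, float]]] = None,
    telomere_len: int = 5000,
    telomere_motif: str = "TTAGGG",
) -> ReferenceGenome:
    """Build a seeded reference with telomere runs and annotated centromeres.

    ``centromere_spec`` maps a chromosome name (``chr1``, ``chr2``, ...) to
    ``(array_length, hor_monomer_count, live_fraction)``.  The alpha-satellite
    array is centred on the chromosome, tiled by HOR rows of
    ``hor_monomer_count`` x 171 bp, each marked live ('L') with probability
    ``live_fraction`` and divergent ('d') otherwise.  The array is annotated
    as alpha_satellite and (emulating a CenSat-style exclusion track) as
    censat_exclude.
    """
    rng = np.random.default_rng(seed)
    centromere_spec = centromere_spec or {}
    sequences: dict[str, str] = {}
    annotations: list[IntervalAnnotation] = []
    for idx, length in enumerate(chrom_lengths, start=1):
        chrom = f"chr{idx}"
        if length < 4 * telomere_len:
            raise ValueError(f"{chrom}: length {length} too short for telomeres")
        seq = list(_random_seq(rng, length))
        tel = (telomere_motif * (telomere_len // len(telomere_motif) + 1))[:telomere_len]
        seq[:telomere_len] = tel
        seq[length - telomere_len :] = revcomp(tel)
        annotations.append(IntervalAnnotation(chrom, 0, telomere_len, "telomere"))
        annotations.append(
            IntervalAnnotation(chrom, length - telomere_len, length, "telomere")
        )
        if chrom in centromere_spec:
            array_len, monomers, live_fraction = centromere_spec[chrom]
            if length < 200_000:
                raise ValueError(
                    f"{chrom}: centromere requested on a chromosome shorter than 200 kb"
                )
            if array_len > length - 2 * telomere_len - 20_000:
                raise ValueError(f"{chrom}: centromere longer than chromosome allows")
            start = (length - array_len) // 2
            monomer = _random_seq(rng, ALPHA_MONOMER_LEN)
            unit = "".join(_mutate(rng, monomer, 0.02) for _ in range(monomers))
            row_len = len(unit)
            pos = start
            while pos < start + array_len:
                end = min(pos + row_len, start + array_len)
                live = rng.random() < live_fraction
                row_seq = unit[: end - pos]
                if not live:
                    row_seq = _mutate(rng, row_seq, 0.05)
                seq[pos:end] = row_seq
                suffix = "L" if live else "d"
                annotations.append(
                    IntervalAnnotation(
                        chrom, pos, end, "hor_row",
                        name=f"S{idx}C{idx}H1{suffix}", score=monomers,
                    )
                )
                pos = end
            annotations.append(
                IntervalAnnotation(chrom, start, start + array_len, "alpha_satellite")
            )
            annotations.append(
                IntervalAnnotation(chrom, start, start + array_len, "censat_exclude")
            )
        sequences[chrom] = "".join(seq)
    return ReferenceGenome(sequences, annotations).validate()


def install_inverted_repeats(
    ref: ReferenceGenome,
    chrom: str,
    locus_start: int,
    locus_end: int,
    sd_pair: tuple[int, float],
    seed: int = 0,
) -> ReferenceGenome:
    """Write an inverted segmental-duplication pair flanking a locus.

    The segment of length ``sd_pair[0]`` ending at ``locus_start`` is copied,
    reverse-complemented, degraded to ``sd_pair[1]`` identity and written at
    ``locus_end`` — the repeat configuration that mediates template switches
    at complex-SV loci.  Returns a new reference; annotations are shared.
    """
    sd_len, identity = sd_pair
    rng = np.random.default_rng(seed)
    seq = ref.sequences[chrom]
    if locus_start - sd_len < 0 or locus_end + sd_len > len(seq):
        raise ValueError("inverted repeat pair does not fit around the locus")
    donor = seq[locus_start - sd_len : locus_start]
    copy = _mutate(rng, revcomp(donor), max(0.0, 1.0 - identity))
    new_seq = seq[:locus_end] + copy + seq[locus_end + sd_len :]
    sequences = dict(ref.sequences)
    sequences[chrom] = new_seq
    return ReferenceGenome(sequences, list(ref.annotations))


# ---------------------------------------------------------------------------
# Event implantation
# ---------------------------------------------------------------------------

def _footprint(v: VariantCall) -> tuple[int, int]:
    return (v.pos, max(v.end, v.pos + 1))


def implant_simple_variants(
    ref: ReferenceGenome,
    counts: Mapping[str, float],
    seed: int,
    size_ranges: Optional[Mapping[str, tuple[int, int]]] = None,
    ploidy: int = 2,
    hom_fraction: float = 0.4,
    avoid_labels: Sequence[str] = ("censat_exclude", "telomere"),
    avoid_intervals: Sequence[tuple[str, int, int]] = (),
    max_retries: int = 1000,
    pad: int = 2,
) -> tuple[dict[str, dict[str, str]], TruthSet]:
    """Implant SNVs and insertions/deletions and realize the haplotypes.

    ``counts`` maps SNV/INS/DEL to an event count (int) or a per-bp rate
    (float < 1).  Events are placed by rejection sampling, largest first,
    mutually non-overlapping and clear of the avoided annotation labels and
    of ``avoid_intervals`` (chrom, start, end) — e.g. a complex-SV footprint.
    Variants of length >= 50 are SV class, 1-49 bp indel class, single-base
    substitutions SNV class.
    """
    rng = np.random.default_rng(seed)
    sizes = dict(DEFAULT_SIZE_RANGES)
    if size_ranges:
        sizes.update(size_ranges)
    genome_len = sum(len(s) for s in ref.sequences.values())
    chroms = list(ref.sequences)
    weights = np.array([len(ref.sequences[c]) for c in chroms], dtype=float)
    weights /= weights.sum()

    requested: list[tuple[str, int]] = []
    for vtype, amount in counts.items():
        if vtype not in sizes:
            raise ValueError(f"unknown variant type {vtype!r}")
        n = int(round(amount * genome_len)) if 0 < amount < 1 else int(amount)
        lo, hi = sizes[vtype]
        for _ in range(n):
            requested.append((vtype, int(rng.integers(lo, hi + 1))))
    requested.sort(key=lambda t: -t[1])  # place largest events first

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for a in ref.annotations:
        if a.label in avoid_labels:
            occupied[a.chrom].append((a.start, a.end))
    for chrom, start, end in avoid_intervals:
        occupied[chrom].append((start, end))

    hap_names = [f"h{i + 1}" for i in range(ploidy)]
    truth = TruthSet()
    for vtype, size in requested:
        placed = False
        for _ in range(max_retries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            L = len(ref.sequences[chrom])
            span = size if vtype != "INS" else 1
            if L - span - 2 <= 1:
                continue
            pos = int(rng.integers(1, L - span - 1))
            lo, hi = pos - pad, pos + span + pad
            if any(s < hi and lo < e for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((lo, hi))
            if ploidy == 1 or rng.random() < hom_fraction:
                haps = tuple(hap_names)
            else:
                haps = (hap_names[int(rng.integers(0, ploidy))],)
            refseq = ref.sequences[chrom]
            if vtype == "SNV":
                refbase = refseq[pos]
                alt = "ACGT".replace(refbase, "")[int(rng.integers(0, 3))]
                v = VariantCall("SNV", chrom, pos, pos + 1, 1, sequence=alt,
                                ref=refbase, info={"haps": haps})
            elif vtype == "INS":
                v = VariantCall("INS", chrom, pos, pos, size,
                                sequence=_random_seq(rng, size), info={"haps": haps})
            else:
                v = VariantCall("DEL", chrom, pos, pos + size, size,
                                sequence=refseq[pos : pos + size], info={"haps": haps})
            truth.simple_variants.append(v)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a {size}-bp {vtype} after {max_retries} retries: "
                "event density too high"
            )
    truth.simple_variants.sort(key=lambda v: (v.chrom, v.pos))
    haplotypes = {h: build_haplotype(ref, truth, h) for h in hap_names}
    return haplotypes, truth


@dataclass
class _CsvGeometry:
    boundaries: list[int]
    run: tuple[int, int]
    left_plus_end: int
    inv_start: int
    inv_end: int
    resume: int


def _csv_geometry(event: CsvEvent) -> _CsvGeometry:
    tpl = event.template
    toks = tpl.tokens
    i, j = tpl.inverted_run()
    b = [event.start]
    for l in tpl.segment_lengths:
        b.append(b[-1] + l)
    for t in range(0, i):
        if toks[t] != "DEL":
            raise ValueError(f"unsupported template {tpl.name!r}: tokens outside the "
                             "inverted run must be DEL")
    for t in range(j + 1, len(toks)):
        if toks[t] != "DEL":
            raise ValueError(f"unsupported template {tpl.name!r}: tokens outside the "
                             "inverted run must be DEL")
    # run must be [INVDUP] INV [INVDUP], with INVDUP only at template edges
    core = list(toks[i : j + 1])
    if core[0] == "INVDUP":
        if i != 0:
            raise ValueError("a leading INVDUP must be the first template token")
        core = core[1:]
    if core and core[-1] == "INVDUP":
        if j != len(toks) - 1:
            raise ValueError("a trailing INVDUP must be the last template token")
        core = core[:-1]
    if core != ["INV"]:
        raise ValueError(
            f"unsupported template {tpl.name!r}: the inverted run must be "
            "[INVDUP-]INV[-INVDUP]"
        )
    left_plus_end = b[i + 1] if toks[i] == "INVDUP" else b[0]
    resume = b[j] if toks[j] == "INVDUP" else b[-1]
    return _CsvGeometry(b, (i, j), left_plus_end, b[i], b[j + 1], resume)


def csv_expected_variants(event: CsvEvent, refseq: Optional[str] = None) -> list[VariantCall]:
    """The simple-variant decomposition a caller should recover for a CSV."""
    tpl = event.template
    toks = tpl.tokens
    g = _csv_geometry(event)
    b = g.boundaries
    i, j = g.run
    out = []

    def seq(s, e):
        return refseq[s:e] if refseq is not None else ""

    for t in range(0, i):
        out.append(VariantCall("DEL", event.chrom, b[t], b[t + 1], b[t + 1] - b[t],
                               sequence=seq(b[t], b[t + 1]), source="inter"))
    if toks[i] == "INVDUP":
        out.append(VariantCall("INVDUP", event.chrom, b[i], b[i + 1], b[i + 1] - b[i],
                               sequence=seq(b[i], b[i + 1]), source="inter"))
    inv_s = b[i + 1] if toks[i] == "INVDUP" else b[i]
    inv_e = b[j] if toks[j] == "INVDUP" else b[j + 1]
    out.append(VariantCall("INV", event.chrom, inv_s, inv_e, inv_e - inv_s,
                           sequence=seq(inv_s, inv_e), source="inter"))
    if toks[j] == "INVDUP":
        out.append(VariantCall("INVDUP", event.chrom, b[j], b[j + 1], b[j + 1] - b[j],
                               sequence=seq(b[j], b[j + 1]), source="inter"))
    for t in range(j + 1, len(toks)):
        out.append(VariantCall("DEL", event.chrom, b[t], b[t + 1], b[t + 1] - b[t],
                               sequence=seq(b[t], b[t + 1]), source="inter"))
    return out


def implant_csv(
    ref: ReferenceGenome,
    template: CsvTemplate,
    locus: tuple[str, int],
    seed: int = 0,
    ploidy: int = 1,
    haplotypes: Sequence[str] = ("h1",),
) -> tuple[dict[str, dict[str, str]], TruthSet]:
    """Implant one complex-SV template at a locus and realize the haplotypes.

    ``locus`` is (chrom, start): the template's segments occupy consecutive
    reference intervals from ``start``.  Raises on unknown tokens, single-token
    (non-complex) templates and loci that do not accommodate the segments.
    """
    template.validate()
    if any(tok in ("INS", "DUP") for tok in template.tokens):
        raise ValueError(
            f"template {template.name!r}: INS/DUP tokens are not supported by "
            "the generator"
        )
    chrom, start = locus
    refseq = ref.sequences[chrom]
    total = sum(template.segment_lengths)
    sd_len = template.sd_pair[0] if template.sd_pair else 0
    if start - sd_len < 1 or start + total + sd_len > len(refseq) - 1:
        raise ValueError("locus does not accommodate the template segments")
    event = CsvEvent(chrom, template, start, [], haplotypes=tuple(haplotypes))
    event.expected_variants = csv_expected_variants(event, refseq)
    _csv_geometry(event)  # validates the token structure
    truth = TruthSet(csv_events=[event])
    hap_names = [f"h{i + 1}" for i in range(ploidy)] if ploidy > 1 else list(haplotypes)
    haps = {h: build_haplotype(ref, truth, h) for h in hap_names}
    return haps, truth


# ---------------------------------------------------------------------------
# Realization: haplotype sequence + exact alignment records from the ledger
# ---------------------------------------------------------------------------

def _realize_chrom(
    chrom: str, refseq: str, events, query_name: str
) -> tuple[str, list[AlignmentRecord]]:
    pieces: list[str] = []
    raw: list[tuple[int, int, int, int, str, list]] = []
    cig: list[tuple[int, str]] = []
    t0 = q0 = 0
    t = q = 0

    def push(n: int, op: str):
        if n <= 0:
            return
        if cig and cig[-1][1] == op:
            cig[-1] = (cig[-1][0] + n, op)
        else:
            cig.append((n, op))

    def flush():
        nonlocal cig, t0, q0
        if cig:
            raw.append((q0, q, t0, t, "+", cig))
        cig = []
        t0, q0 = t, q

    def advance(upto: int):
        nonlocal t, q
        n = upto - t
        if n < 0:
            raise ValueError(f"overlapping events on {chrom} near position {upto}")
        if n > 0:
            pieces.append(refseq[t:upto])
            push(n, "=")
            t = upto
            q += n

    for pos, kind, ev in events:
        if kind == "simple":
            advance(ev.pos)
            if ev.vtype == "SNV":
                pieces.append(ev.sequence)
                push(1, "X")
                t += 1
                q += 1
            elif ev.vtype == "INS":
                pieces.append(ev.sequence)
                push(ev.length, "I")
                q += ev.length
            elif ev.vtype == "DEL":
                push(ev.length, "D")
                t += ev.length
            else:
                raise ValueError(f"cannot realize simple variant type {ev.vtype}")
        else:
            g = _csv_geometry(ev)
            advance(g.left_plus_end)
            flush()
            inv = revcomp(refseq[g.inv_start : g.inv_end])
            pieces.append(inv)
            raw.append((q, q + len(inv), g.inv_start, g.inv_end, "-",
                        [(len(inv), "=")]))
            q += len(inv)
            t = g.resume
            t0, q0 = t, q
    advance(len(refseq))
    flush()
    hapseq = "".join(pieces)
    records = [
        AlignmentRecord(
            query_name=query_name, query_start=qs, query_end=qe, query_len=len(hapseq),
            strand=strand, target_name=chrom, target_start=ts, target_end=te,
            target_len=len(refseq), cigar=c,
        ).validate()
        for qs, qe, ts, te, strand, c in raw
    ]
    return hapseq, records


def build_haplotype(ref: ReferenceGenome, truth: TruthSet, hap: str = "h1") -> dict[str, str]:
    """Apply the ledger to the reference, yielding one haplotype's sequences."""
    out = {}
    for chrom, refseq in ref.sequences.items():
        seq, _ = _realize_chrom(chrom, refseq, truth.events_for(hap, chrom),
                                f"{chrom}_{hap}")
        out[chrom] = seq
    return out


def simulate_alignments(
    ref: ReferenceGenome,
    haplotype: dict[str, str],
    truth: TruthSet,
    hap: str = "h1",
) -> list[AlignmentRecord]:
    """Exact split alignments of a haplotype onto the reference.

    Records are replayed from the ledger and checked against the supplied
    haplotype sequences; a mismatch means ledger and sequence diverged.
    """
    records: list[AlignmentRecord] = []
    for chrom, refseq in ref.sequences.items():
        seq, recs = _realize_chrom(chrom, refseq, truth.events_for(hap, chrom),
                                   f"{chrom}_{hap}")
        if chrom not in haplotype or hash(haplotype[chrom]) != hash(seq) or \
                haplotype[chrom] != seq:
            raise ValueError(f"ledger does not reproduce haplotype sequence for {chrom}")
        records.extend(recs)
    return records


# ---------------------------------------------------------------------------
# Methylation track simulation
# ---------------------------------------------------------------------------

def simulate_methylation(
    ref: ReferenceGenome,
    chrom: str,
    bin_size: int = 5000,
    baseline: float = 0.9,
    cdr_spec: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
    jitter: float = 0.05,
    bin_noise: float = 0.0,
) -> MethylTrack:
    """Binned CpG methylation fractions with implanted hypomethylated dips.

    ``cdr_spec`` lists (start, length, depth) dips; bins inside a dip have
    expected value ``baseline - depth``, partially covered edge bins are
    lowered proportionally.  The bounded symmetric perturbation (``jitter``)
    is a seeded track-level offset; optional per-bin noise (``bin_noise``)
    is available but defaults to 0 because the dip caller's rank-based
    selection makes boundary calls sensitive to independent per-bin noise.
    """
    rng = np.random.default_rng(seed)
    L = len(ref.sequences[chrom])
    for start, length, depth in cdr_spec:
        if start < 0 or start + length > L:
            raise ValueError(f"methylation dip at {start} outside {chrom}")
        if depth < 0:
            raise ValueError("dip depth must be non-negative")
    offset = float(rng.uniform(-jitter, jitter)) if jitter > 0 else 0.0
    bins = []
    for bstart in range(0, L, bin_size):
        bend = min(bstart + bin_size, L)
        drop = 0.0
        for dstart, dlen, depth in cdr_spec:
            ov = min(bend, dstart + dlen) - max(bstart, dstart)
            if ov > 0:
                drop += depth * ov / (bend - bstart)
        val = baseline + offset - drop
        if bin_noise > 0:
            val += float(rng.uniform(-bin_noise, bin_noise))
        bins.append((bstart, bend, float(min(1.0, max(0.0, val)))))
    return MethylTrack(chrom=chrom, bin_size=bin_size, bins=bins).validate()
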