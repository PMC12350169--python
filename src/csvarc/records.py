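"""Core domain records shared by all modules.

Coordinates are 0-based half-open everywhere.  Minus-strand query coordinates
are stored in original (unreversed) query space, matching PAF semantics: the
CIGAR of a minus-strand record describes the alignment of the reverse
complement of ``query[query_start:query_end]`` to the target interval, in
target order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: variant classes recognised throughout the package
VARIANT_TYPES = ("SNV", "INS", "DEL", "INV", "INVDUP", "DUP")

#: minimum length, in bases, for a variant to be a structural variant
SV_MIN_LENGTH = 50


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# CIGAR helpers.  A CIGAR is a list of (length, op) with op in {=, X, I, D}.
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

QUERY_OPS = frozenset("=XI")
TARGET_OPS = frozenset("=XD")


def parse_cigar(text: str) -> list[tuple[int, str]]:
    """Parse a cg:Z-style CIGAR string into (length, op) pairs."""
    ops = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR {text!r} at offset {pos}")
        n = int(m.group(1))
        if n <= 0:
            raise ValueError(f"non-positive CIGAR op length in {text!r}")
        ops.append((n, m.group(2)))
        pos = m.end()
    if pos != len(text) or not ops:
        raise ValueError(f"malformed CIGAR {text!r}")
    return ops


def cigar_str(cigar: list[tuple[int, str]]) -> str:
    return "".join(f"{n}{op}" for n, op in cigar)


def cigar_query_span(cigar) -> int:
    return sum(n for n, op in cigar if op in QUERY_OPS)


def cigar_target_span(cigar) -> int:
    return sum(n for n, op in cigar if op in TARGET_OPS)


def cigar_matches(cigar) -> int:
    return sum(n for n, op in cigar if op == "=")


@dataclass
class AlignmentRecord:
    """One query-to-target alignment with an exact (=/X/I/D) CIGAR."""

    query_name: str
    query_start: int
    query_end: int
    query_len: int
    strand: str
    target_name: str
    target_start: int
    target_end: int
    target_len: int
    cigar: list[tuple[int, str]]
    mapq: int = 60

    def validate(self) -> "AlignmentRecord":
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(f"bad query interval on {self.query_name}")
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(f"bad target interval on {self.target_name}")
        qs = cigar_query_span(self.cigar)
        ts = cigar_target_span(self.cigar)
        if qs != self.query_end - self.query_start:
            raise ValueError(
                f"CIGAR query span {qs} != {self.query_end - self.query_start} "
                f"for {self.query_name}"
            )
        if ts != self.target_end - self.target_start:
            raise ValueError(
                f"CIGAR target span {ts} != {self.target_end - self.target_start} "
                f"for {self.query_name}"
            )
        return self

    @property
    def matches(self) -> int:
        return cigar_matches(self.cigar)

    @property
    def aligned_identity(self) -> float:
        """Fraction of alignment columns that are '=' matches."""
        total = sum(n for n, _ in self.cigar)
        return self.matches / total if total else 0.0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


@dataclass
class VariantCall:
    """A typed variant with dual (target and query) coordinates.

    ``pos``/``end`` are the target interval; insertions are point-like on the
    target (``end == pos``).  ``sequence`` holds inserted bases for INS, the
    deleted reference bases for DEL, the inverted reference segment for
    INV/INVDUP when available, and the alternate base for SNV (the reference
    base is in ``ref``).
    """

    vtype: str
    chrom: str
    pos: int
    end: int
    length: int
    sequence: str = ""
    ref: str = ""
    query_name: str = ""
    query_pos: int = 0
    query_end: int = 0
    source: str = "intra"
    id: str = ""
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.vtype not in VARIANT_TYPES:
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if not self.id:
            self.id = f"{self.chrom}-{self.pos}-{self.vtype}-{self.length}"

    @property
    def vclass(self) -> str:
        """SNV, indel (1-49 bp INS/DEL) or SV (>= 50 bp)."""
        if self.vtype == "SNV":
            return "SNV"
        if self.vtype in ("INS", "DEL") and self.length < SV_MIN_LENGTH:
            return "indel"
        return "SV"

    @property
    def is_sv(self) -> bool:
        return self.vclass == "SV"


@dataclass
class IntervalAnnotation:
    """A BED-like annotated interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    label: str
    strand: str = "."
    score: Optional[float] = None
    name: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class HORRow:
    """One alpha-satellite higher-order-repeat row from an stv_row-style BED."""

    interval: IntervalAnnotation
    hor_name: str
    monomer_count: int = 1
    status: str = "live"

    def __post_init__(self):
        if self.monomer_count < 1:
            raise ValueError("monomer_count must be >= 1")
        if self.status not in ("live", "divergent"):
            raise ValueError(f"bad HOR status {self.status!r}")


@dataclass
class MethylTrack:
    """Binned CpG methylation fractions along one sequence."""

    chrom: str
    bin_size: int
    bins: list[tuple[int, int, float]]  # (start, end, fraction)

    def validate(self) -> "MethylTrack":
        prev_end = -1
        for start, end, frac in self.bins:
            if start >= end or start < prev_end:
                raise ValueError("methylation bins must be sorted, non-overlapping")
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"methylation fraction {frac} outside [0, 1]")
            prev_end = end  # allow gaps but not overlaps
        return self

    def fractions(self):
        return [b[2] for b in self.bins]


@dataclass
class CDRInterval:
    """A centromere dip region: a merged run of below-median methylation bins."""

    chrom: str
    start: int
    end: int
    mean_methylation: float
    n_bins: int
    merged_from: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CSVCall:
    """A resolved complex SV: an ordered signature of simple-SV segments."""

    chrom: str
    signature: str
    variants: list[VariantCall]
    anchors: tuple  # ((start, end), (start, end)) flanking alignment spans
    span: tuple[int, int]
    junction_count: int
    query_name: str = ""

    @property
    def tokens(self) -> list[str]:
        return self.signature.split("-")


@dataclass
class MergedVariant:
    """One non-redundant population variant with carrier bookkeeping."""

    representative: VariantCall
    carriers: frozenset
    members: list[VariantCall] = field(default_factory=list)
    genotypes: dict = field(default_factory=dict)  # hap -> present/absent/missing
    allele_frequency: Optional[float] = None
    af_undefined: bool = False
    support: dict = field(default_factory=dict)  # caller -> bool


@dataclass
class WindowQV:
    """Variant-based Phred quality of one reference window over a diploid pair."""

    chrom: str
    start: int
    end: int
    bp_changes: int
    qv: float
    n_large_errors: int
    capped: bool = False


@dataclass
class KmerQVResult:
    k: int
    total_assembly_kmers: int
    assembly_only_kmers: int
    error_rate: float
    qv: float
    completeness: float
    capped: bool = False


@dataclass
class AvailabilityQV:
    """Highest Phred-scaled similarity of a haplotype to any panel member."""

    target_id: str
    best_panel_match: str
    divergence: float
    qv: float
    capped: bool = False


# ---------------------------------------------------------------------------
# Simulation-side containers
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"^(DEL|INS|INV|INVDUP|DUP)(-(DEL|INS|INV|INVDUP|DUP))*$")


@dataclass
class CsvTemplate:
    """A complex-SV template: an ordered token signature with segment lengths.

    The inverted run is the maximal contiguous run of INV/INVDUP tokens; the
    generator requires exactly one such run, with INVDUP only at the template
    edges (the structures named in published CSV catalogues all satisfy this).
    """

    name: str
    segment_lengths: list[int]
    sd_pair: Optional[tuple[int, float]] = None  # (length, identity)

    @property
    def tokens(self) -> list[str]:
        return self.name.split("-")

    def validate(self) -> "CsvTemplate":
        if not _TOKEN_RE.match(self.name):
            raise ValueError(f"unknown token in template name {self.name!r}")
        toks = self.tokens
        if len(toks) < 2:
            raise ValueError(
                f"template {self.name!r} has a single token: a complex SV spans "
                "more than one repair junction"
            )
        if len(self.segment_lengths) != len(toks):
            raise ValueError("one segment length required per token")
        if any(l < 50 for l in self.segment_lengths):
            raise ValueError("template segments must be >= 50 bp")
        return self

    def inverted_run(self) -> tuple[int, int]:
        """Return [i, j] inclusive indices of the single INV/INVDUP run."""
        toks = self.tokens
        runs = []
        i = 0
        while i < len(toks):
            if toks[i] in ("INV", "INVDUP"):
                j = i
                while j + 1 < len(toks) and toks[j + 1] in ("INV", "INVDUP"):
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        if len(runs) != 1:
            raise ValueError(
                f"template {self.name!r} must contain exactly one contiguous "
                "inverted (INV/INVDUP) run"
            )
        return runs[0]


@dataclass
class CsvEvent:
    """A simulated complex-SV event with its expected simple-variant calls."""

    chrom: str
    template: CsvTemplate
    start: int
    expected_variants: list[VariantCall]
    haplotypes: tuple = ("h1",)

    @property
    def end(self) -> int:
        return self.start + sum(self.template.segment_lengths)


@dataclass
class TruthSet:
    """Ground-truth ledger of implanted events on the reference."""

    simple_variants: list[VariantCall] = field(default_factory=list)
    csv_events: list[CsvEvent] = field(default_factory=list)
    mei_events: list[tuple] = field(default_factory=list)  # (family, chrom, pos, length)

    def events_for(self, hap: str, chrom: str):
        """Simple and CSV events on one haplotype/chromosome, position-sorted."""
        evs: list[tuple[int, str, object]] = []
        for v in self.simple_variants:
            if v.chrom == chrom and hap in v.info.get("haps", ("h1",)):
                evs.append((v.pos, "simple", v))
        for c in self.csv_events:
            if c.chrom == chrom and hap in c.haplotypes:
                evs.append((c.start, "csv", c))
        evs.sort(key=lambda t: t[0])
        return evs

    def extend(self, other: "TruthSet") -> "TruthSet":
        self.simple_variants.extend(other.simple_variants)
        self.csv_events.extend(other.csv_events)
        self.mei_events.extend(other.mei_events)
        return self


@dataclass
class ReferenceGenome:
    """Reference sequences plus annotation tracks (alpha_satellite, telomere,
    censat_exclude, hor_row)."""

    sequences: dict[str, str]
    annotations: list[IntervalAnnotation] = field(default_factory=list)

    def validate(self) -> "ReferenceGenome":
        for a in self.annotations:
            if a.chrom not in self.sequences:
                raise ValueError(f"annotation on unknown chrom {a.chrom}")
            if a.end > len(self.sequences[a.chrom]):
                raise ValueError(f"annotation beyond end of {a.chrom}")
            if a.label == "telomere":
                L = len(self.sequences[a.chrom])
                if a.start != 0 and a.end != L:
                    raise ValueError("telomere annotations only at chromosome ends")
        return self

    def by_label(self, label: str, chrom: Optional[str] = None):
        return [
            a
            for a in self.annotations
            if a.label == label and (chrom is None or a.chrom == chrom)
        ]
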