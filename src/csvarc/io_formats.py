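"""Readers and writers for the standard formats the pipeline touches.

All parsers enforce 0-based half-open coordinates, are total on valid input
and fail loudly (naming the offending line) on invalid input.  Reading is
gzip-transparent.  The variant table is TSV; a minimal VCF export is provided
for interoperability.
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    AlignmentRecord,
    HORRow,
    IntervalAnnotation,
    MethylTrack,
    VariantCall,
    cigar_str,
    parse_cigar,
    revcomp,
)

PathLike = Union[str, Path]


def xopen(path: PathLike, mode: str = "rt"):
    """Open a path, transparently decompressing .gz files."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _lines(source) -> Iterable[tuple[int, str]]:
    if isinstance(source, (str, Path)):
        handle = xopen(source)
        close = True
    else:
        handle, close = source, False
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if line and not line.startswith(("#", "track", "browser")):
                yield lineno, line
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    with xopen(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# PAF with cg:Z CIGAR tag
# ---------------------------------------------------------------------------

def _resolve_m_ops(rec: AlignmentRecord, ref: str, query: str) -> AlignmentRecord:
    """Split M ops into =/X runs using the actual sequences."""
    qseq = query[rec.query_start : rec.query_end]
    if rec.strand == "-":
        qseq = revcomp(qseq)
    tseq = ref[rec.target_start : rec.target_end]
    out: list[tuple[int, str]] = []
    qi = ti = 0

    def push(n, op):
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        else:
            out.append((n, op))

    for n, op in rec.cigar:
        if op == "M":
            for k in range(n):
                push(1, "=" if qseq[qi + k] == tseq[ti + k] else "X")
            qi += n
            ti += n
        else:
            push(n, op)
            if op in "=XI":
                qi += n
            if op in "=XD":
                ti += n
    rec.cigar = out
    return rec


def read_paf(source, sequences: tuple[dict, dict] | None = None) -> list[AlignmentRecord]:
    """Parse PAF records with cg:Z CIGAR tags.

    ``sequences``, if given, is a (target_seqs, query_seqs) pair used to
    resolve 'M' CIGAR ops into =/X; without it, 'M' ops are rejected.
    """
    records = []
    for lineno, line in _lines(source):
        cols = line.split("\t")
        if len(cols) < 12:
            raise ValueError(f"PAF line {lineno}: fewer than 12 columns")
        cg = None
        for tag in cols[12:]:
            if tag.startswith("cg:Z:"):
                cg = tag[5:]
        if cg is None:
            raise ValueError(f"PAF line {lineno}: missing cg:Z CIGAR tag")
        try:
            rec = AlignmentRecord(
                query_name=cols[0],
                query_start=int(cols[2]),
                query_end=int(cols[3]),
                query_len=int(cols[1]),
                strand=cols[4],
                target_name=cols[5],
                target_start=int(cols[7]),
                target_end=int(cols[8]),
                target_len=int(cols[6]),
                cigar=parse_cigar(cg),
                mapq=int(cols[11]),
            )
        except ValueError as exc:
            raise ValueError(f"PAF line {lineno}: {exc}") from exc
        if any(op == "M" for _, op in rec.cigar):
            if sequences is None:
                raise ValueError(
                    f"PAF line {lineno}: 'M' CIGAR ops require sequences to resolve"
                )
            tseqs, qseqs = sequences
            rec = _resolve_m_ops(rec, tseqs[rec.target_name], qseqs[rec.query_name])
        try:
            rec.validate()
        except ValueError as exc:
            raise ValueError(f"PAF line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_paf(records: Iterable[AlignmentRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            total = sum(n for n, _ in r.cigar)
            fields = [
                r.query_name,
                r.query_len,
                r.query_start,
                r.query_end,
                r.strand,
                r.target_name,
                r.target_len,
                r.target_start,
                r.target_end,
                r.matches,
                total,
                r.mapq,
                "cg:Z:" + cigar_str(r.cigar),
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


# ---------------------------------------------------------------------------
# BED-like tracks
# ---------------------------------------------------------------------------

def read_bed_like(source, schema: str = "plain"):
    """Read a tab-separated BED-like track.

    schema='plain'   -> list[IntervalAnnotation] (cols: chrom start end
                        [name] [score] [strand]); label is the name field.
    schema='hor_row' -> list[HORRow]; live/divergent from the trailing 'L'/'d'
                        of the name, monomer count from column 5 when numeric.
    schema='methyl'  -> MethylTrack from bedGraph rows (fraction in [0, 1]).
    """
    if schema not in ("plain", "hor_row", "methyl"):
        raise ValueError(f"unknown schema {schema!r}")
    rows = []
    for lineno, line in _lines(source):
        cols = line.split("\t")
        if len(cols) < 3 + (schema == "methyl"):
            raise ValueError(f"line {lineno}: too few columns for {schema}")
        chrom, start, end = cols[0], int(cols[1]), int(cols[2])
        if start >= end:
            raise ValueError(f"line {lineno}: start >= end")
        rows.append((lineno, chrom, start, end, cols[3:]))

    if schema == "plain":
        out = []
        for lineno, chrom, start, end, rest in rows:
            name = rest[0] if rest else ""
            score = None
            if len(rest) > 1 and rest[1] not in (".", ""):
                score = float(rest[1])
            strand = rest[2] if len(rest) > 2 else "."
            out.append(
                IntervalAnnotation(chrom, start, end, label=name, strand=strand,
                                   score=score, name=name)
            )
        return out

    if schema == "hor_row":
        out = []
        for lineno, chrom, start, end, rest in rows:
            if not rest or not rest[0]:
                raise ValueError(f"line {lineno}: hor_row schema requires a name")
            name = rest[0]
            status = "live" if name.rstrip().endswith("L") else "divergent"
            monomers = 1
            if len(rest) > 1:
                try:
                    monomers = max(1, int(float(rest[1])))
                except ValueError:
                    pass
            iv = IntervalAnnotation(chrom, start, end, label="hor_row", name=name)
            out.append(HORRow(iv, hor_name=name, monomer_count=monomers, status=status))
        return out

    # methyl
    bins = []
    chroms = set()
    for lineno, chrom, start, end, rest in rows:
        frac = float(rest[0])
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"line {lineno}: methylation fraction {frac} outside [0, 1]")
        chroms.add(chrom)
        bins.append((start, end, frac))
    if len(chroms) > 1:
        raise ValueError("methyl schema expects a single chromosome per track")
    bins.sort()
    bin_size = bins[0][1] - bins[0][0] if bins else 0
    track = MethylTrack(chrom=next(iter(chroms)) if chroms else "", bin_size=bin_size,
                        bins=bins)
    return track.validate()


def write_bed(annotations: Iterable[IntervalAnnotation], path: PathLike) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            name = a.name or a.label
            score = "." if a.score is None else f"{a.score:g}"
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{name}\t{score}\t{a.strand}\n")


def write_bedgraph(track: MethylTrack, path: PathLike) -> None:
    with open(path, "w") as fh:
        for start, end, frac in track.bins:
            fh.write(f"{track.chrom}\t{start}\t{end}\t{frac:.4f}\n")


# ---------------------------------------------------------------------------
# Variant tables (TSV) and minimal VCF export
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = [
    "id", "chrom", "pos", "end", "vtype", "vclass", "length",
    "query_name", "query_pos", "query_end", "source", "sequence", "ref",
]


def write_variant_table(variants: Iterable[VariantCall], path_or_stream) -> None:
    rows = [
        {
            "id": v.id, "chrom": v.chrom, "pos": v.pos, "end": v.end,
            "vtype": v.vtype, "vclass": v.vclass, "length": v.length,
            "query_name": v.query_name, "query_pos": v.query_pos,
            "query_end": v.query_end, "source": v.source,
            "sequence": v.sequence, "ref": v.ref,
        }
        for v in variants
    ]
    df = pd.DataFrame(rows, columns=_VARIANT_COLUMNS)
    df.to_csv(path_or_stream, sep="\t", index=False)


def read_variant_table(source) -> list[VariantCall]:
    df = pd.read_csv(source, sep="\t", keep_default_na=False, dtype=str)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VariantCall(
                vtype=row.vtype, chrom=row.chrom, pos=int(row.pos), end=int(row.end),
                length=int(row.length), sequence=row.sequence, ref=row.ref,
                query_name=row.query_name, query_pos=int(row.query_pos),
                query_end=int(row.query_end), source=row.source, id=row.id,
            )
        )
    return out


def write_vcf(variants: Iterable[VariantCall], path: PathLike,
              contigs: dict[str, int] | None = None) -> None:
    """Minimal VCF export (symbolic ALT for non-sequence SV classes)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            if v.vtype == "SNV":
                ref, alt = v.ref or "N", v.sequence or "N"
                pos = v.pos + 1
            elif v.vtype == "INS":
                ref, alt = "N", "N" + v.sequence
                pos = v.pos  # base before the insertion point, 1-based
            elif v.vtype == "DEL":
                ref, alt = "N" + v.sequence, "N"
                pos = v.pos
            else:
                ref, alt = "N", f"<{v.vtype}>"
                pos = v.pos + 1
            svlen = -v.length if v.vtype == "DEL" else v.length
            info = f"END={v.end};SVTYPE={v.vtype};SVLEN={svlen}"
            fh.write(f"{v.chrom}\t{pos}\t{v.id}\t{ref}\t{alt}\t.\tPASS\t{info}\n")
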