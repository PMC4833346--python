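"""Readers and writers for the formats the pipeline exchanges.

Pairwise alignments are normalized to a single internal record
(:class:`AlignmentRecord`) with 0-based half-open intervals and an
explicit strand, whatever the on-disk dialect (PAF or 12-column
BLAST-style tabular).  AGP follows v2.1 (1-based inclusive on disk,
converted at the boundary).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DIALECTS = ("tabular12", "paf")


@dataclass
class AlignmentRecord:
    """One pairwise local alignment in normalized coordinates."""

    query_id: str
    qstart: int
    qend: int
    target_id: str
    tstart: int
    tend: int
    strand: str  # '+' or '-'
    identity: float  # percent, 0-100
    length: int  # aligned block length
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.qend <= self.qstart or self.tend <= self.tstart:
            raise ValueError(f"empty alignment interval: {self}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


class MalformedLineError(ValueError):
    def __init__(self, path, lineno, msg):
        super().__init__(f"{path}:{lineno}: {msg}")


def read_alignments(path, dialect: str = "tabular12") -> list[AlignmentRecord]:
    """Parse an alignment table into normalized records.

    ``tabular12`` is the classic 12-column tabular dialect
    (query, subject, pident, length, mismatch, gapopen, qstart, qend,
    sstart, send, evalue, bitscore) with 1-based inclusive coordinates;
    subject end < start encodes the '-' strand.  ``paf`` is minimap2-style
    PAF with 0-based half-open coordinates.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "paf":
                    records.append(_parse_paf(fields))
                else:
                    records.append(_parse_tab12(fields))
            except (ValueError, IndexError) as exc:
                raise MalformedLineError(path, lineno, str(exc)) from exc
    return records


def _parse_paf(f: Sequence[str]) -> AlignmentRecord:
    if len(f) < 12:
        raise ValueError(f"expected >=12 PAF columns, got {len(f)}")
    matches, block = int(f[9]), int(f[10])
    return AlignmentRecord(
        query_id=f[0], qstart=int(f[2]), qend=int(f[3]),
        target_id=f[5], tstart=int(f[7]), tend=int(f[8]),
        strand=f[4],
        identity=100.0 * matches / block if block else 0.0,
        length=block, score=float(matches),
    )


def _parse_tab12(f: Sequence[str]) -> AlignmentRecord:
    if len(f) < 12:
        raise ValueError(f"expected 12 tabular columns, got {len(f)}")
    qstart, qend = int(f[6]), int(f[7])
    sstart, send = int(f[8]), int(f[9])
    strand = "+"
    if send < sstart:
        strand = "-"
        sstart, send = send, sstart
    return AlignmentRecord(
        query_id=f[0], qstart=qstart - 1, qend=qend,
        target_id=f[1], tstart=sstart - 1, tend=send,
        strand=strand,
        identity=float(f[2]), length=int(f[3]), score=float(f[11]),
    )


def write_alignments(records: Iterable[AlignmentRecord], path, dialect: str = "tabular12") -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for r in records:
            if dialect == "paf":
                fh.write("\t".join(map(str, [
                    r.query_id, r.qend, r.qstart, r.qend, r.strand,
                    r.target_id, r.tend, r.tstart, r.tend,
                    int(round(r.score)), r.length, 255,
                ])) + "\n")
            else:
                sstart, send = r.tstart + 1, r.tend
                if r.strand == "-":
                    sstart, send = send, sstart
                mismatch = int(round(r.length * (1 - r.identity / 100.0)))
                fh.write("\t".join(map(str, [
                    r.query_id, r.target_id, f"{r.identity:.2f}", r.length,
                    mismatch, 0, r.qstart + 1, r.qend, sstart, send,
                    0.0, f"{r.score:.1f}",
                ])) + "\n")


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(reads: Iterable[tuple[str, str]], path, quality: int = 30) -> None:
    """Write (name, sequence) pairs with a flat quality score."""
    with open(path, "w") as fh:
        for name, s in reads:
            fh.write(f"@{name}\n{s}\n+\n{chr(quality + 33) * len(s)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# AGP v2.1

@dataclass
class AgpRow:
    object_id: str
    object_beg: int  # 1-based inclusive, as on disk
    object_end: int
    part_number: int
    component_type: str  # 'W' contig, 'N' gap
    component_id: str | None = None
    component_beg: int | None = None
    component_end: int | None = None
    orientation: str | None = None
    gap_length: int | None = None


def write_agp(rows: Iterable[AgpRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for r in rows:
            if r.component_type == "N":
                tail = [r.gap_length, "scaffold", "yes", "align_genus"]
            else:
                tail = [r.component_id, r.component_beg, r.component_end, r.orientation]
            fh.write("\t".join(map(str, [
                r.object_id, r.object_beg, r.object_end, r.part_number,
                r.component_type, *tail,
            ])) + "\n")


def read_agp(path) -> list[AgpRow]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                base = dict(object_id=f[0], object_beg=int(f[1]), object_end=int(f[2]),
                            part_number=int(f[3]), component_type=f[4])
                if f[4] in ("N", "U"):
                    rows.append(AgpRow(**base, gap_length=int(f[5])))
                else:
                    rows.append(AgpRow(**base, component_id=f[5],
                                       component_beg=int(f[6]), component_end=int(f[7]),
                                       orientation=f[8]))
            except (ValueError, IndexError) as exc:
                raise MalformedLineError(path, lineno, str(exc)) from exc
    return rows


# ---------------------------------------------------------------------------
# BED and small tables

def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(map(str, iv)) + "\n")


def append_manifest(path, entry: dict) -> None:
    with open(path, "a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")
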