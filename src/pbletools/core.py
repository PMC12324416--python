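"""Shared sequence/interval data model and plain-text genomics IO.

All coordinates are 0-based half-open throughout the package; GFF3 (1-based,
closed) is converted at the read/write boundary. Sequences are uppercase over
the alphabet {A, C, G, T, N}; other IUPAC ambiguity codes are rejected rather
than silently remapped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


def _validate_sequence(seq: str, name: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - ALPHABET
    if bad:
        raise SequenceAlphabetError(
            f"{name} contains characters outside A/C/G/T/N: {sorted(bad)}"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N. Involution."""
    seq = _validate_sequence(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """Named contigs of uppercase A/C/G/T/N.

    ``contigs`` preserves insertion order (FASTA record order). ``lengths``
    is derived and always consistent with the stored strings.
    """

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"empty sequence for contig {name!r}")
            cleaned[name] = _validate_sequence(seq, name=f"contig {name!r}")
        self.contigs = cleaned

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Subsequence [start, end) of a contig (0-based half-open)."""
        seq = self.contigs[contig]
        if not 0 <= start < end <= len(seq):
            raise ValueError(
                f"coordinates [{start},{end}) out of range for contig "
                f"{contig!r} of length {len(seq)}"
            )
        return seq[start:end]


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open, optionally stranded/labelled."""

    contig: str
    start: int
    end: int
    strand: str = "."
    label: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end (got [{self.start},{self.end}))"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Lowercase input is normalised to uppercase. Duplicate contig names and
    empty records are errors.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name {record.id!r} in {path}")
        seq = str(record.seq)
        if not seq:
            raise ValueError(f"empty record {record.id!r} in {path}")
        contigs[record.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTQ as a list of (read name, sequence); qualities are ignored."""
    return [
        (record.id, str(record.seq).upper())
        for record in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) pairs as FASTQ with uniform placeholder quality."""
    with open(path, "w") as handle:
        for name, seq in reads:
            handle.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------


def read_intervals(path: str | Path, format: str = "bed") -> list[Interval]:
    """Read intervals from BED (0-based half-open) or GFF3 (1-based closed).

    GFF3 coordinates are converted on read so the in-memory representation
    is always 0-based half-open.
    """
    if format == "bed":
        return _read_bed(path)
    if format == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown interval format {format!r}")


def _read_bed(path: str | Path) -> list[Interval]:
    intervals = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: BED needs >= 3 columns")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else "."
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(
                Interval(contig, start, end, strand=strand, label=label, score=score)
            )
    return intervals


def _read_gff3(path: str | Path) -> list[Interval]:
    intervals = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{line_no}: GFF3 needs 9 columns")
            contig = fields[0]
            start1, end1 = int(fields[3]), int(fields[4])
            if start1 < 1:
                raise ValueError(f"{path}:{line_no}: GFF3 start must be >= 1")
            score = None if fields[5] == "." else float(fields[5])
            strand = fields[6] if fields[6] in {"+", "-"} else "."
            label = fields[2]
            for attr in fields[8].split(";"):
                if attr.startswith(("Name=", "ID=")):
                    label = attr.split("=", 1)[1]
                    break
            intervals.append(
                Interval(contig, start1 - 1, end1, strand=strand, label=label, score=score)
            )
    return intervals


def write_intervals(
    intervals: Iterable[Interval],
    path: str | Path,
    format: str = "bed",
    source: str = "pbletools",
) -> None:
    """Write intervals as BED6 or GFF3 (coordinates converted on write)."""
    with open(path, "w") as handle:
        if format == "bed":
            for iv in intervals:
                score = "." if iv.score is None else f"{iv.score:g}"
                handle.write(
                    f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.label}\t{score}\t{iv.strand}\n"
                )
        elif format == "gff3":
            handle.write("##gff-version 3\n")
            for iv in intervals:
                score = "." if iv.score is None else f"{iv.score:g}"
                handle.write(
                    f"{iv.contig}\t{source}\t{iv.label}\t{iv.start + 1}\t{iv.end}"
                    f"\t{score}\t{iv.strand}\t.\tName={iv.label}\n"
                )
        else:
            raise ValueError(f"unknown interval format {format!r}")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_table(path: str | Path) -> pd.DataFrame:
    """Tab-separated table with a header row; '.' denotes a missing value."""
    return pd.read_csv(path, sep="\t", na_values=["."])


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=".")


def genome_lengths_from_tsv(path: str | Path) -> dict[str, int]:
    """Two-column (contig, length) TSV without header, bedtools-genome style."""
    lengths = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            lengths[name] = int(length)
    return lengths
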