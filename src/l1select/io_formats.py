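"""Readers and writers for the standard formats the toolkit touches.

All internal coordinates are 0-based, half-open (the BED convention). The
only place 1-based inclusive coordinates appear is the RepeatMasker ``.out``
parser, which converts at the boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "GenomicInterval",
    "RepeatAnnotation",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_repeatmasker_out",
    "read_chrom_sizes",
]

GENOME_ALPHABET = frozenset("ACGTN")
PRIMER_ALPHABET = frozenset("ACGT")

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, uppercase canonical."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record has empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")
        bad = set(self.seq) - GENOME_ALPHABET
        if bad:
            raise FormatError(
                f"sequence record {self.id!r} contains non-IUPAC characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with optional strand and name."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"negative coordinate: {self.chrom}:{self.start}")
        if self.end <= self.start:
            raise FormatError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Base pairs shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def with_name(self, name: str) -> "GenomicInterval":
        return replace(self, name=name)


@dataclass(frozen=True)
class RepeatAnnotation:
    """One annotated repeat copy (e.g. a RepeatMasker record)."""

    interval: GenomicInterval
    repeat_name: str
    repeat_class: str = ""
    repeat_family: str = ""

    def __post_init__(self) -> None:
        if not self.repeat_name:
            raise FormatError("repeat annotation with empty repeat_name")

    @property
    def length(self) -> int:
        return self.interval.length


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def normalize_sequence(raw: str, record_id: str, alphabet=GENOME_ALPHABET) -> str:
    """Uppercase, map RNA U to T, and validate against ``alphabet``."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - alphabet
    if bad:
        raise FormatError(
            f"record {record_id!r} contains illegal characters: {sorted(bad)}"
        )
    return seq


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a FASTA file (plain or gzip) into validated records.

    Lowercase is folded to uppercase and U is mapped to T. Raises
    :class:`FormatError` on an empty file, duplicate ids, or characters
    outside {A,C,G,T,N}, naming the offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = normalize_sequence(str(rec.seq), rec.id)
            records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 80) -> None:
    with open(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")


def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read BED3–BED6 (tab-separated) into 0-based half-open intervals.

    The BED placeholder name ``.`` is read back as an empty name so that
    ``read_bed(write_bed(x)) == x``.
    """
    intervals: list[GenomicInterval] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative coordinate {start}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, strand=strand, name=name))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    """Write BED6 (BED3 when every interval has no name and no strand)."""
    intervals = list(intervals)
    bed3 = all(iv.name == "" and iv.strand == "." for iv in intervals)
    with open(path, "wt") as out:
        for iv in intervals:
            if bed3:
                out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.name if iv.name else "."
                out.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
                )


def read_repeatmasker_out(path: PathLike) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` file.

    Query coordinates are 1-based inclusive in the file and are converted to
    0-based half-open (begin-1, end). The RepeatMasker complement strand
    marker ``C`` maps to ``-``. Header lines (anything before the first row
    starting with a numeric score) are skipped.
    """
    annotations: list[RepeatAnnotation] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            fields = line.split()
            if not fields or not fields[0].lstrip("-").isdigit():
                continue  # header / blank
            if len(fields) < 14:
                raise FormatError(
                    f"{path}:{lineno}: expected >=14 RepeatMasker columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[4]
            begin, end = int(fields[5]), int(fields[6])
            strand = "-" if fields[8] == "C" else fields[8]
            repeat_name = fields[9]
            cls_fam = fields[10].split("/", 1)
            repeat_class = cls_fam[0]
            repeat_family = cls_fam[1] if len(cls_fam) > 1 else ""
            interval = GenomicInterval(
                chrom, begin - 1, end, strand=strand, name=repeat_name
            )
            annotations.append(
                RepeatAnnotation(interval, repeat_name, repeat_class, repeat_family)
            )
    return annotations


def read_annotation(path: PathLike) -> list[RepeatAnnotation]:
    """Read repeat annotation from either RepeatMasker ``.out`` or BED.

    For BED input the name field carries the subfamily label; class/family
    are left empty.
    """
    path = Path(path)
    if path.name.endswith((".out", ".out.gz")):
        return read_repeatmasker_out(path)
    return [
        RepeatAnnotation(iv, iv.name or "unknown")
        for iv in read_bed(path)
    ]


def read_chrom_sizes(path: PathLike) -> dict[str, int]:
    """Read a two-column ``<chrom>\\t<size>`` file."""
    sizes: dict[str, int] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected chrom and size")
            sizes[fields[0]] = int(fields[1])
    return sizes
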