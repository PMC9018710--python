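"""Readers, writers, and coordinate conventions for the formats the pipeline touches.

Conventions
-----------
* All interval coordinates are BED-style: 0-based, half-open ``[start, end)``.
* The 5'-most base of a plus-strand read is ``start``; of a minus-strand read
  it is ``end - 1``.
* Sequences are stored internally in the DNA alphabet; reporting layers render
  T as U.
* Reads containing N in an interrogated window are excluded from that
  statistic only, never globally.

All text readers are gzip-transparent: a path ending in ``.gz`` is opened
through :mod:`gzip`.
"""

from __future__ import annotations

import gzip
import io
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import revcomp

__all__ = [
    "ReadRecord",
    "SequenceSet",
    "Interval",
    "IntervalSet",
    "TrackRecord",
    "Track",
    "read_reads",
    "write_reads",
    "extract_five_prime_trinucleotide",
    "extract_downstream_sequence",
]

MIN_READ_LENGTH = 15
MAX_READ_LENGTH = 70


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class ReadRecord:
    """One aligned small-RNA read.

    ``count`` is the read multiplicity (collapsed duplicates); coordinates are
    0-based half-open on ``contig``.
    """

    contig: str
    start: int
    end: int
    strand: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if not MIN_READ_LENGTH <= self.length <= MAX_READ_LENGTH:
            raise ValueError(
                f"read length {self.length} outside plausible small-RNA range "
                f"{MIN_READ_LENGTH}-{MAX_READ_LENGTH}"
            )
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic position of the 5'-most base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic position of the 3'-most base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def downstream_of_three_prime(self) -> int:
        """Genomic position immediately past the 3' end (transcript orientation)."""
        return self.end if self.strand == "+" else self.start - 1


class SequenceSet(Mapping[str, str]):
    """Immutable mapping from identifier to an upper-case DNA sequence."""

    def __init__(self, sequences: Mapping[str, str]):
        seqs = {}
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
            seqs[str(name)] = str(seq).upper()
        self._seqs = seqs

    def __getitem__(self, key: str) -> str:
        return self._seqs[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceSet":
        with _open_text(path) as handle:
            records = list(SeqIO.parse(handle, "fasta"))
        names = [r.id for r in records]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate identifiers in {path}")
        return cls({r.id: str(r.seq) for r in records})

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self._seqs.items()
        ]
        with _open_text(path, "wt") as handle:
            SeqIO.write(records, handle, "fasta")


@dataclass(frozen=True)
class Interval:
    """A stranded genomic interval in 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    strand: str = "+"
    name: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """An ordered collection of :class:`Interval` (disjointness not required)."""

    def __init__(self, intervals: Iterable[Interval] = ()):
        self.intervals = list(intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i: int) -> Interval:
        return self.intervals[i]

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        ivs = []
        with _open_text(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
                contig, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                strand = fields[5] if len(fields) > 5 else "+"
                ivs.append(Interval(contig, start, end, strand, name))
        return cls(ivs)

    def to_bed(self, path: str | Path) -> None:
        with _open_text(path, "wt") as handle:
            for iv in self.intervals:
                handle.write(
                    f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
                )


@dataclass(frozen=True)
class TrackRecord:
    """One per-base score, e.g. a phyloP value at a genomic position."""

    contig: str
    position: int
    value: float


class Track:
    """Per-base real-valued track, one value per (contig, position)."""

    def __init__(self, values: Mapping[tuple[str, int], float] | None = None):
        self._values: dict[tuple[str, int], float] = dict(values or {})

    def __len__(self) -> int:
        return len(self._values)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._values

    def get(self, contig: str, position: int) -> float | None:
        return self._values.get((contig, position))

    def set(self, contig: str, position: int, value: float) -> None:
        self._values[(contig, position)] = float(value)

    def items(self):
        return self._values.items()

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "Track":
        """Read a bedGraph-like track, expanding intervals to per-base values."""
        values: dict[tuple[str, int], float] = {}
        with _open_text(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
                contig, start, end, value = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    float(fields[3]),
                )
                for pos in range(start, end):
                    values[(contig, pos)] = value
        return cls(values)

    def to_bedgraph(self, path: str | Path) -> None:
        """Write per-base lines (no run-length merging; lossless and simple)."""
        with _open_text(path, "wt") as handle:
            for (contig, pos), value in sorted(self._values.items()):
                handle.write(f"{contig}\t{pos}\t{pos + 1}\t{value:g}\n")


def read_reads(path: str | Path, format: str = "bed6") -> list[ReadRecord]:
    """Read aligned small-RNA reads from a BED-like file.

    ``format='bed6'`` maps standard BED6 columns (name/score ignored) to one
    read of count 1 per line. ``format='bed6+count'`` expects a 7th integer
    column carrying the read multiplicity (a reconstruction of the collapsed
    "bed2-like" dialects common for small-RNA data).
    """
    if format not in ("bed6", "bed6+count"):
        raise ValueError(f"unknown read format {format!r}")
    reads: list[ReadRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            min_cols = 7 if format == "bed6+count" else 6
            if len(fields) < min_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, got {len(fields)}"
                )
            try:
                contig = fields[0]
                start, end = int(fields[1]), int(fields[2])
                strand = fields[5]
                count = int(fields[6]) if format == "bed6+count" else 1
                reads.append(ReadRecord(contig, start, end, strand, count))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return reads


def write_reads(reads: Iterable[ReadRecord], path: str | Path, format: str = "bed6+count") -> None:
    """Write reads as BED6 (+ optional count column)."""
    if format not in ("bed6", "bed6+count"):
        raise ValueError(f"unknown read format {format!r}")
    with _open_text(path, "wt") as handle:
        for i, r in enumerate(reads):
            base = f"{r.contig}\t{r.start}\t{r.end}\tr{i}\t0\t{r.strand}"
            if format == "bed6+count":
                handle.write(f"{base}\t{r.count}\n")
            else:
                handle.write(base + "\n")


def _clean_kmer(kmer: str, k: int) -> str | None:
    if len(kmer) != k or "N" in kmer:
        return None
    return kmer


def extract_five_prime_trinucleotide(read: ReadRecord, seqs: SequenceSet) -> str | None:
    """The trinucleotide starting at the read's 5' end (DNA alphabet).

    Returns ``None`` when the 3-base window leaves the sequence or contains N.
    Raises ``KeyError`` if the read's contig is absent from ``seqs``.
    """
    seq = seqs[read.contig]
    if read.strand == "+":
        kmer = seq[read.start : read.start + 3]
    else:
        lo = read.end - 3
        if lo < 0:
            return None
        kmer = revcomp(seq[lo : read.end])
    return _clean_kmer(kmer, 3)


def extract_downstream_sequence(read: ReadRecord, seqs: SequenceSet, k: int) -> str | None:
    """The k-mer immediately downstream of the read's 3' end (transcript direction).

    For a plus-strand read this is ``seq[end:end+k]``; for a minus-strand read
    it is the reverse complement of ``seq[start-k:start]``. Returns ``None`` at
    sequence boundaries or when the window contains N.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = seqs[read.contig]
    if read.strand == "+":
        kmer = seq[read.end : read.end + k]
    else:
        lo = read.start - k
        if lo < 0:
            return None
        kmer = revcomp(seq[lo : read.start])
    return _clean_kmer(kmer, k)
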