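"""Canonical in-memory genomic records shared by every pipeline stage.

All coordinates are 0-based half-open on the forward strand of a named
chromosome; 1-based formats (repeatMasker ``.out``) are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

#: Closed vocabulary of retroelement families; anything else maps to "other".
FAMILIES = (
    "ERV1",
    "ERVK",
    "ERVL",
    "ERVL-MaLR",
    "LINE1",
    "SINE-B1",
    "SINE-B2",
    "SINE-B4",
    "other",
)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class RepeatCopy:
    """One annotated repeat interval with family/subfamily labels."""

    interval: GenomicInterval
    family: str
    subfamily: str
    copy_id: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"family {self.family!r} not in the closed vocabulary {FAMILIES}"
            )

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class AlignedRead:
    """A single aligned read reduced to its genomic interval."""

    interval: GenomicInterval
    sample_id: str = ""

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class ReadTable(Sequence):
    """Columnar container for aligned reads.

    Behaves as a sequence of :class:`AlignedRead` but stores coordinates in
    numpy arrays so that million-read simulations stay cheap. One table holds
    reads of a single sample.
    """

    def __init__(
        self,
        chroms: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        sample_id: str = "",
    ) -> None:
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if not (len(chroms) == len(starts) == len(ends)):
            raise ValueError("chroms, starts, ends must have equal length")
        if len(starts) and np.any(starts >= ends):
            raise ValueError("every read must satisfy start < end")
        self.chroms = chroms
        self.starts = starts
        self.ends = ends
        self.sample_id = sample_id

    @classmethod
    def from_reads(cls, reads: Iterable[AlignedRead], sample_id: str = "") -> "ReadTable":
        reads = list(reads)
        return cls(
            np.array([r.chrom for r in reads], dtype=object),
            np.array([r.start for r in reads], dtype=np.int64),
            np.array([r.end for r in reads], dtype=np.int64),
            sample_id=sample_id or (reads[0].sample_id if reads else ""),
        )

    def __len__(self) -> int:
        return len(self.starts)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return ReadTable(self.chroms[i], self.starts[i], self.ends[i], self.sample_id)
        return AlignedRead(
            GenomicInterval(self.chroms[i], int(self.starts[i]), int(self.ends[i])),
            sample_id=self.sample_id,
        )

    def __iter__(self) -> Iterator[AlignedRead]:
        for i in range(len(self)):
            yield self[i]

    def __repr__(self) -> str:
        return f"ReadTable(n={len(self)}, sample_id={self.sample_id!r})"


def as_read_table(reads, sample_id: str = "") -> ReadTable:
    """Coerce a ReadTable or iterable of AlignedRead into a ReadTable."""
    if isinstance(reads, ReadTable):
        return reads
    return ReadTable.from_reads(reads, sample_id=sample_id)
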