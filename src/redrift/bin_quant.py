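"""Fixed-width genome binning, read counting, and enrichment normalization.

The genome is tiled with uniform bins (default 500 bp; the final bin of each
chromosome is truncated at the chromosome end and kept). Each read is
assigned to exactly one bin by its midpoint, so integer counts are conserved:
assigned + unassigned = input reads. Counts are converted to FPKM
(count / (bin kb x library millions)) and optionally to log2(FPKM + pseudocount).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, ReadTable, as_read_table

log = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 500


@dataclass(frozen=True)
class BinFrame:
    """A deterministic tiling of chromosomes with uniform-width bins.

    Chromosome order follows the order of ``chrom_lengths``; within a
    chromosome bins are ordered by position. Zero-length chromosomes are
    skipped with a warning.
    """

    chrom_lengths: dict[str, int]
    bin_width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self):
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        kept = {}
        for chrom, L in self.chrom_lengths.items():
            if L <= 0:
                log.warning("skipping zero-length chromosome %r", chrom)
                continue
            kept[chrom] = int(L)
        object.__setattr__(self, "chrom_lengths", kept)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def n_bins_per_chrom(self) -> dict[str, int]:
        w = self.bin_width
        return {c: -(-L // w) for c, L in self.chrom_lengths.items()}

    @property
    def offsets(self) -> dict[str, int]:
        out, acc = {}, 0
        for c, n in self.n_bins_per_chrom.items():
            out[c] = acc
            acc += n
        return out

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_per_chrom.values())

    def bin_lengths(self) -> np.ndarray:
        """True bp length of each bin (final per-chromosome bin may be short)."""
        out = np.full(self.n_bins, self.bin_width, dtype=np.int64)
        for c, L in self.chrom_lengths.items():
            rem = L % self.bin_width
            if rem:
                out[self.offsets[c] + self.n_bins_per_chrom[c] - 1] = rem
        return out

    def intervals(self) -> list[GenomicInterval]:
        out = []
        w = self.bin_width
        for c, L in self.chrom_lengths.items():
            for s in range(0, L, w):
                out.append(GenomicInterval(c, s, min(s + w, L)))
        return out

    def bin_index(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Global bin index for each (chrom, position); -1 for unknown chroms
        or positions beyond the chromosome end."""
        idx = np.full(len(positions), -1, dtype=np.int64)
        offsets = self.offsets
        for c in np.unique(chroms.astype(object)):
            if c not in self.chrom_lengths:
                continue
            m = chroms == c
            pos = positions[m]
            ok = (pos >= 0) & (pos < self.chrom_lengths[c])
            sub = np.full(pos.shape, -1, dtype=np.int64)
            sub[ok] = offsets[c] + pos[ok] // self.bin_width
            idx[m] = sub
        return idx

    @classmethod
    def from_intervals(cls, bins: Sequence[GenomicInterval]) -> "BinFrame":
        """Reconstruct a frame from a tiling produced by :func:`partition_bins`."""
        if not bins:
            raise ValueError("empty bin list")
        widths = {b.length for b in bins}
        width = max(widths)
        lengths: dict[str, int] = {}
        for b in bins:
            lengths[b.chrom] = max(lengths.get(b.chrom, 0), b.end)
        frame = cls(lengths, width)
        if frame.n_bins != len(bins):
            raise ValueError("bins do not form a uniform tiling")
        return frame


def partition_bins(
    chrom_lengths: Mapping[str, int], bin_width: int = DEFAULT_BIN_WIDTH
) -> list[GenomicInterval]:
    """Tile chromosomes with fixed-width bins (last bin truncated)."""
    return BinFrame(dict(chrom_lengths), bin_width).intervals()


@dataclass
class BinCountMatrix:
    """Raw read counts per genomic bin, one column per sample."""

    frame: BinFrame
    counts: np.ndarray  # (n_bins, n_samples) nonnegative ints
    sample_ids: list[str]
    library_sizes: np.ndarray  # total input reads per sample
    unassigned: np.ndarray  # reads not assigned to any bin, per sample

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 1:
            self.counts = self.counts[:, None]
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        self.unassigned = np.asarray(self.unassigned, dtype=np.int64)
        if self.counts.shape != (self.frame.n_bins, len(self.sample_ids)):
            raise ValueError("counts shape does not match frame/samples")
        if np.any(self.counts.sum(axis=0) > self.library_sizes):
            raise ValueError("column sums exceed library sizes")

    @property
    def bins(self) -> list[GenomicInterval]:
        return self.frame.intervals()

    def sample(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        ivs = self.bins
        df = pd.DataFrame(
            {
                "chrom": [b.chrom for b in ivs],
                "start": [b.start for b in ivs],
                "end": [b.end for b in ivs],
            }
        )
        for j, s in enumerate(self.sample_ids):
            df[s] = self.counts[:, j]
        return df


@dataclass
class NormalizedMethylome:
    """Per-bin enrichment values on the FPKM or log2(FPKM + pc) scale."""

    frame: BinFrame
    values: np.ndarray  # (n_bins, n_samples)
    sample_ids: list[str]
    scale: str  # {"fpkm", "log2"}
    pseudocount: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.scale not in ("fpkm", "log2"):
            raise ValueError("scale must be 'fpkm' or 'log2'")
        if self.scale == "fpkm" and np.any(self.values < 0):
            raise ValueError("FPKM values must be nonnegative")

    @property
    def bins(self) -> list[GenomicInterval]:
        return self.frame.intervals()

    def sample(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]


def count_reads_in_bins(
    reads,
    bins: Sequence[GenomicInterval] | BinFrame,
    sample_id: str | None = None,
    extend_bp: int = 0,
) -> BinCountMatrix:
    """Count reads into bins by read midpoint (floor((start + end) / 2)).

    Each read lands in exactly one bin; reads on unknown chromosomes are
    tallied as unassigned so totals reconcile. ``extend_bp`` optionally
    extends each read 3'-ward (rightward for strandless intervals) toward
    the fragment length before the midpoint is taken; default off.
    """
    frame = bins if isinstance(bins, BinFrame) else BinFrame.from_intervals(list(bins))
    table = as_read_table(reads)
    sid = sample_id or table.sample_id or "sample"
    mid = (table.starts + table.ends + extend_bp) // 2
    idx = frame.bin_index(table.chroms, mid)
    assigned = idx[idx >= 0]
    counts = np.bincount(assigned, minlength=frame.n_bins).astype(np.int64)
    unassigned = int(len(table) - len(assigned))
    if unassigned:
        log.info("%d reads unassigned (unknown chrom/out of range)", unassigned)
    return BinCountMatrix(
        frame=frame,
        counts=counts[:, None],
        sample_ids=[sid],
        library_sizes=np.array([len(table)]),
        unassigned=np.array([unassigned]),
    )


def build_count_matrix(
    reads_by_sample: Mapping[str, ReadTable], frame: BinFrame
) -> BinCountMatrix:
    """Count several samples onto a shared bin frame."""
    cols, libs, unas, ids = [], [], [], []
    for sid, reads in reads_by_sample.items():
        m = count_reads_in_bins(reads, frame, sample_id=sid)
        cols.append(m.counts[:, 0])
        libs.append(m.library_sizes[0])
        unas.append(m.unassigned[0])
        ids.append(sid)
    return BinCountMatrix(
        frame=frame,
        counts=np.column_stack(cols),
        sample_ids=ids,
        library_sizes=np.array(libs),
        unassigned=np.array(unas),
    )


def fpkm_normalize(matrix: BinCountMatrix) -> NormalizedMethylome:
    """FPKM = count / (bin length in kb x library size in millions)."""
    if np.any(matrix.library_sizes <= 0):
        raise ValueError("library sizes must be positive for FPKM")
    kb = matrix.frame.bin_lengths() / 1000.0
    millions = matrix.library_sizes / 1e6
    values = matrix.counts / (kb[:, None] * millions[None, :])
    return NormalizedMethylome(
        frame=matrix.frame,
        values=values,
        sample_ids=list(matrix.sample_ids),
        scale="fpkm",
    )


def log2_with_pseudocount(
    methylome: NormalizedMethylome, pseudocount: float = 1.0
) -> NormalizedMethylome:
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if methylome.scale != "fpkm":
        raise ValueError("input must be on the fpkm scale")
    return NormalizedMethylome(
        frame=methylome.frame,
        values=np.log2(methylome.values + pseudocount),
        sample_ids=list(methylome.sample_ids),
        scale="log2",
        pseudocount=pseudocount,
    )


def distribution_summary(methylome: NormalizedMethylome) -> pd.DataFrame:
    """Per-sample mean, variance (ddof=1), quartiles (linear interpolation),
    and IQR of the per-bin values."""
    if methylome.values.shape[0] < 1:
        raise ValueError("need at least one bin")
    rows = {}
    for j, sid in enumerate(methylome.sample_ids):
        v = methylome.values[:, j]
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows[sid] = {
            "mean": float(np.mean(v)),
            "variance": float(np.var(v, ddof=1)) if len(v) > 1 else 0.0,
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "iqr": float(q3 - q1),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def fpkm_for_count(count: float, bin_width: int, library_size: int) -> float:
    """FPKM value a raw count corresponds to at a given depth (helper for the
    'average read count ~= 10' mid-stratum anchor)."""
    return count / ((bin_width / 1000.0) * (library_size / 1e6))
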