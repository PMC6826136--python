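"""Body-scaled methylation meta-profiles over repeat copies.

Each copy's span is resampled onto a fixed number of body bins between its
start (S) and end (E) sites, oriented 5'->3' (minus-strand copies are
reversed), using exact length-weighted averaging of the 500-bp bin track.
Copies are decomposed into two clusters (k = 2 k-means on the youngest
sample, assignments frozen across ages), fractionated by length (>1/>3/>5 kb),
split into evolutionarily active LINE1 subfamilies vs the rest, and profiled
for CpG-dinucleotide density over 10 equal parts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .bin_quant import NormalizedMethylome
from .intervals import RepeatCopy

log = logging.getLogger(__name__)

ACTIVE_L1_SUBFAMILIES = frozenset({"L1Md_A", "L1Md_Gf", "L1Md_T"})


@dataclass
class MetaProfileMatrix:
    """copies x body-position bins of signal, one slab per sample."""

    copy_ids: list[str]
    n_body_bins: int
    values: dict[str, np.ndarray]  # sample -> (n_copies, n_body_bins)
    sample_ids: list[str]
    n_excluded_short: int = 0

    def sample(self, sample_id: str) -> np.ndarray:
        return self.values[sample_id]

    @property
    def n_copies(self) -> int:
        return len(self.copy_ids)


@dataclass
class ClusterAssignment:
    """Two-group copy assignment; cluster 1 is the higher-methylation group."""

    labels: dict[str, int]  # copy_id -> {1, 2}
    cluster_means: tuple[float, float]  # overall mean signal of clusters 1, 2

    def of(self, copy_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.labels[c] for c in copy_ids])


def scaled_profile_matrix(
    methylome: NormalizedMethylome,
    copies: Sequence[RepeatCopy],
    n_body_bins: int = 100,
    min_length: int | None = None,
    samples: Sequence[str] | None = None,
) -> MetaProfileMatrix:
    """Resample the bin track onto each copy's body.

    The copy span is divided into ``n_body_bins`` equal segments; a segment's
    value is the length-weighted mean per-bp signal of the overlapping genome
    bins (computed exactly from the cumulative integral of the track).
    Minus-strand rows are reversed so column 0 is always the 5' end. Copies
    shorter than ``min_length`` (default ``n_body_bins`` bp, so every segment
    spans >= 1 bp) are excluded and counted.
    """
    if not copies:
        raise ValueError("no copies supplied")
    if n_body_bins < 2:
        raise ValueError("n_body_bins must be >= 2")
    if min_length is None:
        min_length = n_body_bins
    if min_length < n_body_bins:
        raise ValueError("min_length must be >= n_body_bins")
    samples = list(samples) if samples is not None else list(methylome.sample_ids)

    frame = methylome.frame
    bin_len = frame.bin_lengths()
    # per-chromosome cumulative integral of the per-bp signal
    cums: dict[str, dict[str, np.ndarray]] = {}
    for chrom in frame.chroms:
        off = frame.offsets[chrom]
        n = frame.n_bins_per_chrom[chrom]
        lens = bin_len[off : off + n]
        edges = np.concatenate(([0], np.cumsum(lens)))
        per_sample = {}
        for s in samples:
            v = methylome.sample(s)[off : off + n]
            per_sample[s] = np.concatenate(([0.0], np.cumsum(v * lens)))
        cums[chrom] = {"edges": edges.astype(float), **per_sample}

    kept = [c for c in copies if c.length >= min_length]
    n_excluded = len(copies) - len(kept)
    if not kept:
        raise ValueError(
            f"all {len(copies)} copies shorter than min_length={min_length}"
        )
    if n_excluded:
        log.info("excluded %d copies shorter than %d bp", n_excluded, min_length)

    values = {s: np.empty((len(kept), n_body_bins)) for s in samples}
    for i, c in enumerate(kept):
        xs = c.start + c.length * np.arange(n_body_bins + 1) / n_body_bins
        seg = np.diff(xs)
        edges = cums[c.chrom]["edges"]
        for s in samples:
            cum = cums[c.chrom][s]
            cx = np.interp(xs, edges, cum)
            row = np.diff(cx) / seg
            if c.strand == "-":
                row = row[::-1]
            values[s][i] = row
    return MetaProfileMatrix(
        copy_ids=[c.copy_id for c in kept],
        n_body_bins=n_body_bins,
        values=values,
        sample_ids=samples,
        n_excluded_short=n_excluded,
    )


def kmeans2_cluster(
    matrix: MetaProfileMatrix,
    reference_sample: str,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterAssignment:
    """k = 2 Lloyd k-means (k-means++ seeding, best of ``n_restarts``) on the
    reference sample's raw profile rows; cluster 1 is relabeled to the higher
    overall mean. The assignment is then fixed and reused across ages.
    """
    X = matrix.sample(reference_sample)
    if X.shape[0] < 2:
        raise ValueError("need at least two copies to cluster")
    if len(np.unique(X, axis=0)) < 2:
        log.warning("identical profile rows: single effective cluster")
        labels = {cid: 1 for cid in matrix.copy_ids}
        return ClusterAssignment(labels, (float(X.mean()), float("nan")))
    km = KMeans(
        n_clusters=2,
        init="k-means++",
        n_init=n_restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    means = np.array([X[km.labels_ == k].mean() for k in (0, 1)])
    hi = int(np.argmax(means))
    labels = {
        cid: 1 if lab == hi else 2 for cid, lab in zip(matrix.copy_ids, km.labels_)
    }
    return ClusterAssignment(labels, (float(means[hi]), float(means[1 - hi])))


@dataclass(frozen=True)
class ClusterProfile:
    mean: np.ndarray
    sd: np.ndarray
    n: int


def cluster_mean_profiles(
    matrix: MetaProfileMatrix, assignment: ClusterAssignment
) -> dict[tuple[str, int], ClusterProfile]:
    """Column-wise mean +/- sd per cluster and sample. Empty clusters yield
    NaN profiles with a warning."""
    lab = assignment.of(matrix.copy_ids)
    out = {}
    for s in matrix.sample_ids:
        X = matrix.sample(s)
        for k in (1, 2):
            rows = X[lab == k]
            if len(rows) == 0:
                log.warning("cluster %d empty for sample %s", k, s)
                nan = np.full(matrix.n_body_bins, np.nan)
                out[(s, k)] = ClusterProfile(nan, nan.copy(), 0)
            else:
                out[(s, k)] = ClusterProfile(
                    rows.mean(axis=0),
                    rows.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(matrix.n_body_bins),
                    len(rows),
                )
    return out


def filter_by_length(
    copies: Sequence[RepeatCopy], thresholds: Sequence[int] = (1000, 3000, 5000)
) -> dict[int, list[RepeatCopy]]:
    """Nested strict-greater length fractions (>1/>3/>5 kb by default)."""
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds) or sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be positive and increasing")
    return {t: [c for c in copies if c.length > t] for t in thresholds}


def subfamily_partition(
    copies: Sequence[RepeatCopy],
    active_names: Iterable[str] = ACTIVE_L1_SUBFAMILIES,
) -> tuple[list[RepeatCopy], list[RepeatCopy]]:
    """Exhaustive, disjoint split into (active, rest) by exact subfamily name."""
    active_names = set(active_names)
    active = [c for c in copies if c.subfamily in active_names]
    rest = [c for c in copies if c.subfamily not in active_names]
    return active, rest


def cpg_density_profile(
    copies: Sequence[RepeatCopy],
    cpg_positions: Mapping[str, np.ndarray],
    n_parts: int = 10,
) -> pd.DataFrame:
    """Mean CpG density (per bp) over ``n_parts`` equal body parts, per family.

    CpG positions are 0-based positions of the C on the + strand; parts are
    oriented 5'->3' (strand-aware). Copies shorter than ``n_parts`` bp are
    excluded and counted in the ``n_copies``/``n_excluded`` attrs.
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    n_excluded = 0
    for c in copies:
        if c.length < n_parts:
            n_excluded += 1
            continue
        pos = cpg_positions.get(c.chrom, np.array([], dtype=np.int64))
        lo, hi = np.searchsorted(pos, [c.start, c.end])
        rel = (pos[lo:hi] - c.start) / c.length
        part = np.minimum((rel * n_parts).astype(int), n_parts - 1)
        if c.strand == "-":
            part = n_parts - 1 - part
        density = np.bincount(part, minlength=n_parts) / (c.length / n_parts)
        sums[c.family] = sums.get(c.family, np.zeros(n_parts)) + density
        counts[c.family] = counts.get(c.family, 0) + 1
    df = pd.DataFrame(
        {fam: sums[fam] / counts[fam] for fam in sums},
        index=[f"part_{i + 1}" for i in range(n_parts)],
    ).T
    df.attrs["n_copies"] = counts
    df.attrs["n_excluded"] = n_excluded
    return df
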