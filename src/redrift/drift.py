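"""Baseline-rank stratified methylation-drift statistics.

Bins are stratified by their enrichment in the youngest (baseline) sample:
the top-ranked high-methylation stratum, a mid stratum of bins nearest a
target level (anchored at roughly 10 raw reads per bin), and the bottom-ranked
low-methylation stratum. Per-stratum trajectories are the mean log2 fold
change of each older age against the baseline, with the per-month drift rate
expressed in fold space (a 1.38-fold cumulative change over 20 months is a
rate of 1.38/20 ~= 0.07-fold per month).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bin_quant import NormalizedMethylome

DEFAULT_STRATUM_SIZES = {"high": 100_000, "mid": 100_000, "low": 1_048_575}


@dataclass(frozen=True)
class DriftStratum:
    label: str  # {"high", "mid", "low"}
    bin_indices: np.ndarray
    n: int

    def __post_init__(self):
        object.__setattr__(self, "bin_indices", np.asarray(self.bin_indices, dtype=np.int64))
        if self.n != len(self.bin_indices):
            raise ValueError("n must equal the number of bin indices")


@dataclass
class DriftTrajectory:
    """Mean log2 fold change vs the baseline age for one stratum."""

    stratum: str
    sample_ids: list[str]  # baseline first
    mean_log2_fc: np.ndarray  # baseline entry exactly 0
    sd_log2_fc: np.ndarray
    fold_magnitude: np.ndarray  # 2**|mean log2 FC|
    direction: np.ndarray  # sign of mean log2 FC
    rate_per_month: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "stratum": self.stratum,
                "sample": self.sample_ids,
                "mean_log2_fc": self.mean_log2_fc,
                "sd_log2_fc": self.sd_log2_fc,
                "fold_magnitude": self.fold_magnitude,
                "direction": self.direction,
            }
        )
        if self.rate_per_month is not None:
            df["rate_per_month"] = self.rate_per_month
        return df


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    n: int


def scale_stratum_sizes(
    n_bins: int,
    n_high: int = DEFAULT_STRATUM_SIZES["high"],
    n_mid: int = DEFAULT_STRATUM_SIZES["mid"],
    n_low: int = DEFAULT_STRATUM_SIZES["low"],
) -> tuple[int, int, int]:
    """Scale the default stratum sizes proportionally onto a smaller bin frame.

    The genome-scale defaults (100,000 / 100,000 / 1,048,575) exceed small
    synthetic frames; when their sum exceeds ``n_bins`` all three are scaled
    by the same factor so they partition the frame (remainder goes to low).
    """
    total = n_high + n_mid + n_low
    if total <= n_bins:
        return n_high, n_mid, n_low
    f = n_bins / total
    h, m = max(1, int(n_high * f)), max(1, int(n_mid * f))
    return h, m, n_bins - h - m


def stratify_by_baseline(
    methylome: NormalizedMethylome,
    baseline_sample: str,
    n_high: int,
    n_mid: int,
    n_low: int,
    mid_target_level: float,
) -> dict[str, DriftStratum]:
    """Partition bins into high / mid / low strata by baseline enrichment.

    Bins are ranked once by baseline value (descending, ties by genomic
    order): high = the first ``n_high`` of that ranking, low = the last
    ``n_low``, and mid = the ``n_mid`` remaining bins whose baseline values
    are nearest ``mid_target_level`` (ties again by genomic order). A single
    ranking guarantees the strata partition even among tied values, and the
    result is deterministic.
    """
    v = methylome.sample(baseline_sample)
    n = len(v)
    if n_high + n_mid + n_low > n:
        raise ValueError(
            f"requested strata ({n_high}+{n_mid}+{n_low}) exceed {n} bins"
        )
    order = np.arange(n)
    desc = np.lexsort((order, -v))
    high_idx = np.sort(desc[:n_high])
    low_idx = np.sort(desc[n - n_low :])
    taken = np.zeros(n, dtype=bool)
    taken[high_idx] = True
    taken[low_idx] = True
    remaining = order[~taken]
    near = np.lexsort((remaining, np.abs(v[remaining] - mid_target_level)))
    mid_idx = np.sort(remaining[near[:n_mid]])
    return {
        "high": DriftStratum("high", high_idx, len(high_idx)),
        "mid": DriftStratum("mid", mid_idx, len(mid_idx)),
        "low": DriftStratum("low", low_idx, len(low_idx)),
    }


def drift_rate(total_fold_change: float, months: float) -> float:
    """Per-month drift rate: cumulative fold change divided by months.

    Exactly linear in the fold change and inversely proportional to months;
    e.g. a 1.38-fold cumulative change over 20 months is 0.069-fold/month.
    """
    if months <= 0:
        raise ValueError("months must be positive")
    if total_fold_change < 0:
        raise ValueError("total_fold_change must be >= 0 (direction is separate)")
    return total_fold_change / months


def stratum_trajectory(
    methylome: NormalizedMethylome,
    strata: Mapping[str, DriftStratum] | Sequence[DriftStratum],
    baseline_sample: str,
    comparison_samples: Sequence[str],
    pseudocount: float = 1.0,
    months: Mapping[str, float] | None = None,
) -> list[DriftTrajectory]:
    """Per-stratum mean +/- sd log2((v_age + pc) / (v_base + pc)) trajectories.

    ``months`` optionally maps each comparison sample to the month figure used
    for the per-month rate (the source analyses divide by the age in months).
    """
    if isinstance(strata, Mapping):
        strata = list(strata.values())
    base = methylome.sample(baseline_sample) + pseudocount
    out = []
    for st in strata:
        if st.n == 0:
            raise ValueError(f"stratum {st.label!r} is empty")
        idx = st.bin_indices
        means, sds = [0.0], [0.0]
        for s in comparison_samples:
            fc = np.log2((methylome.sample(s)[idx] + pseudocount) / base[idx])
            means.append(float(np.mean(fc)))
            sds.append(float(np.std(fc, ddof=1)) if len(fc) > 1 else 0.0)
        means = np.array(means)
        folds = 2.0 ** np.abs(means)
        rates = None
        if months is not None:
            rates = np.array(
                [0.0]
                + [
                    drift_rate(float(f), months[s])
                    for f, s in zip(folds[1:], comparison_samples)
                ]
            )
        out.append(
            DriftTrajectory(
                stratum=st.label,
                sample_ids=[baseline_sample, *comparison_samples],
                mean_log2_fc=means,
                sd_log2_fc=np.array(sds),
                fold_magnitude=folds,
                direction=np.sign(means),
                rate_per_month=rates,
            )
        )
    return out


def methylome_regression(
    methylome: NormalizedMethylome,
    x_sample: str,
    y_sample: str,
    pseudocount: float = 1.0,
) -> RegressionResult:
    """OLS of y on x on the log2 scale (log2(v + pc) applied to fpkm input)."""
    x = methylome.sample(x_sample)
    y = methylome.sample(y_sample)
    if methylome.scale == "fpkm":
        x = np.log2(x + pseudocount)
        y = np.log2(y + pseudocount)
    finite = np.isfinite(x) & np.isfinite(y)
    x, y = x[finite], y[finite]
    if len(x) < 2:
        raise ValueError("need at least two bins with finite values")
    if np.var(x) == 0:
        raise ValueError("zero variance in x sample")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pearson_r=float(res.rvalue),
        n=len(x),
    )


def stratum_test(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t test (Welch-Satterthwaite df), two-sided.

    Zero variance in both groups with equal means returns (0, 1) by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return (np.inf if np.mean(b) < np.mean(a) else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass(frozen=True)
class FoldChangeHistogram:
    edges: np.ndarray
    counts: np.ndarray  # len(edges) - 1
    underflow: int
    overflow: int

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.underflow + self.overflow


def foldchange_histogram(
    methylome: NormalizedMethylome,
    sample_a: str,
    sample_b: str,
    edges: Sequence[float],
    pseudocount: float = 1.0,
) -> FoldChangeHistogram:
    """Histogram of per-bin log2 fold changes (b vs a) over the given edges;
    values outside the edges go to under/overflow buckets."""
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least two edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    fc = np.log2(
        (methylome.sample(sample_b) + pseudocount)
        / (methylome.sample(sample_a) + pseudocount)
    )
    fc = fc[np.isfinite(fc)]
    counts, _ = np.histogram(fc, bins=edges)
    underflow = int(np.sum(fc < edges[0]))
    overflow = int(np.sum(fc > edges[-1]))
    # np.histogram includes the right edge in the last bin; keep it there.
    return FoldChangeHistogram(edges, counts, underflow, overflow)
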