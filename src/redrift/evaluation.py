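"""End-to-end study evaluations: the summary numbers the analysis reports.

Thin orchestration over the pipeline modules, shared by the analysis scripts
and the acceptance checks so that every reported quantity is computed one
way. All functions recompute from a :class:`~redrift.simulate.SimulatedStudy`
(or a seed) at run time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .bin_quant import (
    distribution_summary,
    fpkm_for_count,
    log2_with_pseudocount,
)
from .diffexpr import (
    CountTable,
    classify_expression_phases,
    differential_features,
)
from .drift import (
    methylome_regression,
    scale_stratum_sizes,
    stratify_by_baseline,
    stratum_trajectory,
)
from .metaprofile import (
    cluster_mean_profiles,
    cpg_density_profile,
    filter_by_length,
    kmeans2_cluster,
    scaled_profile_matrix,
    subfamily_partition,
)
from .simulate import AgingSimSpec, SimulatedStudy, simulate_expression_counts, simulate_study


def stratum_trajectories(study: SimulatedStudy, tissue: str) -> dict[str, np.ndarray]:
    """High/mid/low mean log2 FC vs the 2-m baseline for one tissue.

    Strata sizes are the genome-scale defaults scaled onto the bin frame; the
    mid stratum is anchored at the enrichment corresponding to ~10 raw reads.
    """
    fp = study.fpkm[tissue]
    ages = study.spec.ages_months
    base = study.sample_name(ages[0])
    older = [study.sample_name(a) for a in ages[1:]]
    n_high, n_mid, n_low = scale_stratum_sizes(study.frame.n_bins)
    mid_target = fpkm_for_count(10, study.spec.bin_width, study.spec.library_size)
    strata = stratify_by_baseline(fp, base, n_high, n_mid, n_low, mid_target)
    return {
        t.stratum: t.mean_log2_fc[1:]
        for t in stratum_trajectory(fp, strata, base, older)
    }


@dataclass
class DriftRecovery:
    high: np.ndarray  # mean log2 FC at the older ages, drifting tissue
    low: np.ndarray
    mid: np.ndarray
    control_max_abs: float  # worst |mean log2 FC| over control strata/ages

    @property
    def signs_correct(self) -> bool:
        return bool(np.all(self.high < 0) and np.all(self.low > 0))

    @property
    def accelerates(self) -> bool:
        return bool(
            abs(self.high[-1]) > abs(self.high[0])
            and abs(self.low[-1]) > abs(self.low[0])
        )


def drift_sign_recovery(seed: int) -> DriftRecovery:
    """Simulate one study and measure stratified drift in both tissues."""
    study = simulate_study(AgingSimSpec(seed=seed), with_expression=False)
    muscle = stratum_trajectories(study, "muscle")
    control = stratum_trajectories(study, "tcell")
    return DriftRecovery(
        high=muscle["high"],
        low=muscle["low"],
        mid=muscle["mid"],
        control_max_abs=float(max(np.abs(v).max() for v in control.values())),
    )


def variance_and_slopes(study: SimulatedStudy) -> dict[str, float]:
    """Log2-scale per-sample variance and inter-age regression slopes."""
    fp = study.fpkm["muscle"]
    ages = study.spec.ages_months
    s = [study.sample_name(a) for a in ages]
    summary = distribution_summary(log2_with_pseudocount(fp))
    r_mid = methylome_regression(fp, s[0], s[1])
    r_old = methylome_regression(fp, s[0], s[2])
    return {
        "variance_young": float(summary.loc[s[0], "variance"]),
        "variance_old": float(summary.loc[s[-1], "variance"]),
        "slope_young_vs_mid": r_mid.slope,
        "slope_young_vs_old": r_old.slope,
        "r2_young_vs_mid": r_mid.r_squared,
        "r2_young_vs_old": r_old.r_squared,
    }


def cluster_recovery(
    study: SimulatedStudy,
    family: str = "LINE1",
    min_length: int = 1000,
    seed: int = 7,
) -> dict[str, float]:
    """Two-cluster decomposition of one family vs the planted labels.

    Clusters on the log2(FPKM + 1) track of the youngest muscle sample (raw
    FPKM rows are dominated by the heavy-tailed 5' peak columns); reports the
    adjusted Rand index and the with-age change of each cluster's mean
    profile (cluster 1 should lose, cluster 2 gain).
    """
    track = log2_with_pseudocount(study.fpkm["muscle"])
    ages = study.spec.ages_months
    young, old = study.sample_name(ages[0]), study.sample_name(ages[-1])
    copies = [c for c in study.copies if c.family == family]
    mat = scaled_profile_matrix(track, copies, min_length=min_length)
    assignment = kmeans2_cluster(mat, young, seed=seed)
    truth = [study.truth.cluster[cid] for cid in mat.copy_ids]
    ari = adjusted_rand_score(truth, assignment.of(mat.copy_ids))
    prof = cluster_mean_profiles(mat, assignment)
    return {
        "ari": float(ari),
        "n_copies": mat.n_copies,
        "cluster1_change": float(prof[(old, 1)].mean.mean() - prof[(young, 1)].mean.mean()),
        "cluster2_change": float(prof[(old, 2)].mean.mean() - prof[(young, 2)].mean.mean()),
    }


def size_fraction_effect(study: SimulatedStudy, family: str = "LINE1") -> dict[str, float]:
    """Mean-profile decrease (young minus old, FPKM) of >5 kb vs <1 kb
    cluster-1 copies, plus the active-vs-rest LINE1 contrast on >5 kb copies."""
    fp = study.fpkm["muscle"]
    ages = study.spec.ages_months
    young, old = study.sample_name(ages[0]), study.sample_name(ages[-1])
    c1 = [
        c
        for c in study.copies
        if c.family == family and study.truth.cluster[c.copy_id] == 1
    ]
    fractions = filter_by_length(c1)
    long_cp = fractions[5000]
    short_cp = [c for c in c1 if c.length < 1000]

    def mean_drop(copies):
        mat = scaled_profile_matrix(fp, copies, min_length=100)
        return float(mat.sample(young).mean() - mat.sample(old).mean()), float(
            mat.sample(young).mean()
        )

    drop_long, base_long = mean_drop(long_cp)
    drop_short, base_short = mean_drop(short_cp)
    active, rest = subfamily_partition(long_cp)
    drop_active, base_active = mean_drop(active)
    drop_rest, base_rest = mean_drop(rest)
    return {
        "drop_gt5kb": drop_long,
        "drop_lt1kb": drop_short,
        "baseline_active": base_active,
        "baseline_rest": base_rest,
        "drop_active": drop_active,
        "drop_rest": drop_rest,
        "n_gt5kb": len(long_cp),
        "n_active": len(active),
    }


def cpg_decile_summary(study: SimulatedStudy) -> dict[str, dict[str, float]]:
    """Per-family CpG-density decile trend: Spearman rank correlation of the
    mean density across the 10 parts and a chi-square uniformity test on the
    pooled per-part CpG counts (parts are equal-length, so pooled counts are
    multinomial-uniform under uniform placement)."""
    dens = cpg_density_profile(study.copies, study.cpgs, n_parts=10)
    out = {}
    for family in dens.index:
        rho = stats.spearmanr(np.arange(10), dens.loc[family]).statistic
        counts = _pooled_part_counts(study, family)
        chi = stats.chisquare(counts)
        out[family] = {
            "spearman_rho": float(rho),
            "uniformity_p": float(chi.pvalue),
            "n_cpgs": int(counts.sum()),
        }
    return out


def _pooled_part_counts(study: SimulatedStudy, family: str, n_parts: int = 10) -> np.ndarray:
    counts = np.zeros(n_parts, dtype=np.int64)
    for c in study.copies:
        if c.family != family or c.length < n_parts:
            continue
        pos = study.cpgs.get(c.chrom, np.array([], dtype=np.int64))
        lo, hi = np.searchsorted(pos, [c.start, c.end])
        rel = (pos[lo:hi] - c.start) / c.length
        part = np.minimum((rel * n_parts).astype(int), n_parts - 1)
        if c.strand == "-":
            part = n_parts - 1 - part
        counts += np.bincount(part, minlength=n_parts)
    return counts


def null_de_type1_rate(seed: int, n_features: int = 1000) -> float:
    """Fraction of features with p < 0.05 between two ages of a null table
    (no planted expression effects)."""
    spec = AgingSimSpec(seed=seed, expression_phase_effects=(0.0, 0.0))
    study = simulate_study(spec, with_expression=False)
    table, groups, _ = simulate_expression_counts(
        spec, study.copies, study.truth.cluster, seed + 10_007
    )
    table = table.iloc[:n_features]
    ages = spec.ages_months
    de = differential_features(CountTable(table, groups), ages[0], ages[1])
    return float((de["p"] < 0.05).mean())


def expression_recovery(study: SimulatedStudy) -> dict[str, float]:
    """Two-phase classification sensitivity and late-phase DE recovery.

    Sensitivity: fraction of planted down_up features recovered by
    :func:`classify_expression_phases`. Late DE: fraction of large (>3 kb)
    cluster-1 copies called significantly up between the two older ages.
    """
    if study.expression is None:
        raise ValueError("study was simulated without expression")
    ages = list(study.spec.ages_months)
    table, groups = study.expression, study.expression_groups
    pred = classify_expression_phases(table, groups, ages)
    truth = pd.Series(study.truth.expression_phase)
    down_up = truth.index[truth == "down_up"]
    sensitivity = float((pred[down_up] == "down_up").mean())

    de = differential_features(CountTable(table, groups), ages[1], ages[2])
    large_c1 = [
        c.copy_id
        for c in study.copies
        if c.length > 3000 and study.truth.cluster[c.copy_id] == 1
    ]
    late = de.loc[large_c1]
    late_recovery = float((late["significant"] & (late["log2_fc"] > 0)).mean())

    retro = [c.copy_id for c in study.copies]
    early = differential_features(CountTable(table, groups), ages[0], ages[1])
    return {
        "two_phase_sensitivity": sensitivity,
        "late_de_recovery": late_recovery,
        "n_down_up": int(len(down_up)),
        "n_large_cluster1": len(large_c1),
        "frac_retro_down_early": float((early.loc[retro, "log2_fc"] < 0).mean()),
        "frac_retro_up_late": float((de.loc[retro, "log2_fc"] > 0).mean()),
    }
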