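"""Ground-truth aging simulator: toy genome, repeat annotation, methylomes
with planted bidirectional drift, MBD-capture-like reads, and RNA-seq-like
retroelement counts.

The model plants the structure the downstream statistics are meant to
recover:

* repeat copies of eight retroelement families placed without overlap,
  with length mixtures dominated by <1 kb copies plus a >5 kb tail;
* per-family body-methylation templates (e.g. a strong 5' LTR peak in ERV1,
  peaks at both ends in ERVK, a single 5' UTR peak in LINE1), scaled by a
  two-cluster copy assignment (high ~0.8 vs low ~0.2 plateau);
* "regression toward the mean" drift: bins above the genome-mean methylation
  decay multiplicatively per month, bins below relax toward the mean, so
  drift contracts variance and never overshoots;
* a non-drifting control tissue;
* MBD-seq-like reads whose per-bin expectation is methylation x CpG content,
  drawn negative-binomially and placed uniformly inside their bin;
* a repress-then-derepress retroelement expression trajectory across three
  ages, with the late up-shift concentrated in large (>3 kb) high-methylation
  copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bin_quant import BinFrame, BinCountMatrix, NormalizedMethylome, build_count_matrix, fpkm_normalize
from .diffexpr import two_phase_classification
from .drift import scale_stratum_sizes
from .intervals import GenomicInterval, ReadTable, RepeatCopy

N_TEMPLATE_BINS = 100


def _bumps(peaks: list[tuple[float, float, float]], base: float) -> np.ndarray:
    """Build a [0,1] body template from Gaussian bumps (center, width, height)."""
    x = (np.arange(N_TEMPLATE_BINS) + 0.5) / N_TEMPLATE_BINS
    y = np.full(N_TEMPLATE_BINS, base)
    for center, width, height in peaks:
        y = np.maximum(y, base + (height - base) * np.exp(-0.5 * ((x - center) / width) ** 2))
    return np.clip(y, 0.0, 1.0)


def default_family_templates() -> dict[str, np.ndarray]:
    """Per-family body-methylation templates over 100 body bins.

    ERV1: strong 5' LTR, weak 3' LTR; ERVK: peaks at both ends, 5' stronger;
    ERVL: weak 5', strong 3'; LINE1: single 5' UTR peak; SINEs and MaLR:
    flat moderate plateaus.
    """
    return {
        "ERV1": _bumps([(0.06, 0.05, 1.0), (0.94, 0.05, 0.55)], base=0.40),
        "ERVK": _bumps([(0.06, 0.05, 0.95), (0.94, 0.05, 0.70)], base=0.40),
        "ERVL": _bumps([(0.06, 0.05, 0.45), (0.94, 0.05, 0.90)], base=0.40),
        "ERVL-MaLR": _bumps([], base=0.50),
        "LINE1": _bumps([(0.05, 0.04, 1.0)], base=0.40),
        "SINE-B1": _bumps([], base=0.55),
        "SINE-B2": _bumps([], base=0.50),
        "SINE-B4": _bumps([], base=0.45),
    }


_SUBFAMILY_POOL = {
    "ERV1": ("MuRRS-int", "RLTR6"),
    "ERVK": ("IAPEz-int", "IAPLTR1a", "RLTR10"),
    "ERVL": ("MERVL-int", "MT2_Mm"),
    "ERVL-MaLR": ("MTA_Mm", "ORR1A1"),
    "LINE1": ("L1_Mus3", "L1Md_F2", "Lx5"),
    "SINE-B1": ("B1_Mm",),
    "SINE-B2": ("B2_Mm1a",),
    "SINE-B4": ("B4A",),
}


@dataclass
class AgingSimSpec:
    """Full parameterization of the synthetic genome, methylome, drift, and
    read models. Defaults define the study conditions: three ages (2, 20,
    28 months), a drifting muscle and a stable T-cell control, pooled MBD
    libraries per age, and triplicate RNA-seq."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    bin_width: int = 500
    ages_months: tuple[int, ...] = (2, 20, 28)
    tissues: tuple[str, ...] = ("muscle", "tcell")
    drift_enabled: dict[str, bool] = field(
        default_factory=lambda: {"muscle": True, "tcell": False}
    )
    n_copies_per_family: dict[str, int] = field(
        default_factory=lambda: {
            "LINE1": 600,
            "ERV1": 250,
            "ERVK": 250,
            "ERVL": 200,
            "ERVL-MaLR": 200,
            "SINE-B1": 200,
            "SINE-B2": 150,
            "SINE-B4": 150,
        }
    )
    # mixture weights for {short <1 kb, mid 1-5 kb, long >5 kb} copy lengths
    length_distribution: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "LINE1": (0.75, 0.15, 0.10),
            "ERV1": (0.70, 0.20, 0.10),
            "ERVK": (0.70, 0.20, 0.10),
            "ERVL": (0.75, 0.20, 0.05),
            "ERVL-MaLR": (0.85, 0.15, 0.0),
            "SINE-B1": (1.0, 0.0, 0.0),
            "SINE-B2": (1.0, 0.0, 0.0),
            "SINE-B4": (1.0, 0.0, 0.0),
        }
    )
    length_ranges: tuple[tuple[int, int], ...] = ((150, 999), (1000, 5000), (5001, 8000))
    cluster2_fraction: float = 0.2  # low-methylation copies, within 10%-30%
    family_templates: dict[str, np.ndarray] = field(default_factory=default_family_templates)
    plateau_high: float = 0.8
    plateau_low: float = 0.2
    plateau_jitter: tuple[float, float] = (0.75, 1.15)  # per-copy biological spread
    active_plateau: float = 0.95  # evolutionarily active LINE1 (cluster 1)
    active_subfamilies: frozenset = frozenset({"L1Md_A", "L1Md_Gf", "L1Md_T"})
    active_fraction_of_long_line1: float = 0.5
    background_beta: tuple[float, float] = (2.0, 18.0)  # mean 0.1
    cpg_rate_repeat: float = 0.02  # CpGs per bp inside copies
    cpg_rate_background: float = 0.004
    cpg_content_cv: float = 0.08  # per-copy spread around the family rate
    erv1_5prime_cpg_fraction: float = 0.75
    drift_rate_loss: float = 0.0175  # per-month fractional loss above the mean
    drift_rate_gain: float = 0.012  # per-month relaxation toward the mean below it
    library_size: int = 1_440_000  # ~72 reads/bin, one pooled library per age
    nb_dispersion: float = 1000.0  # NB size: near-Poisson single-library noise
    read_length: int = 100
    cpg_epsilon: float = 0.1
    n_replicates_rnaseq: int = 3
    n_background_genes: int = 4000  # stable features anchoring size factors
    expression_base_mean: float = 100.0
    expression_base_sigma: float = 0.5
    expression_phase_effects: tuple[float, float] = (-1.0, 1.5)  # early down, late up (log2)
    expression_late_other_scale: float = 0.5  # late up-shift fraction for non-large/cluster-2
    expression_nb_dispersion: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if any(L <= 0 for L in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if list(self.ages_months) != sorted(set(self.ages_months)):
            raise ValueError("ages must be strictly increasing")
        if not (0 < self.cluster2_fraction < 1):
            raise ValueError("cluster2_fraction must be in (0, 1)")
        for name, tpl in self.family_templates.items():
            tpl = np.asarray(tpl)
            if np.any(tpl < 0) or np.any(tpl > 1):
                raise ValueError(f"template {name} has values outside [0, 1]")
        for rate in (self.drift_rate_loss, self.drift_rate_gain):
            if rate < 0:
                raise ValueError("drift rates must be >= 0")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")

    def frame(self) -> BinFrame:
        return BinFrame(dict(self.chrom_lengths), self.bin_width)


@dataclass
class GroundTruth:
    """Planted labels used as the test oracle for every downstream stage."""

    cluster: dict[str, int]  # copy_id -> {1, 2}
    baseline_methylation: np.ndarray  # per bin, [0, 1]
    stratum: np.ndarray  # per bin, {"high", "mid", "low"}
    active_copy_ids: frozenset
    expression_phase: dict[str, str] = field(default_factory=dict)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_repeat_annotation(
    spec: AgingSimSpec, rng=None
) -> tuple[list[RepeatCopy], dict[str, np.ndarray]]:
    """Place repeat copies uniformly at random without overlap and scatter
    CpG positions (dense inside copies, sparse background; ERV1 CpGs biased
    to the 5' half).

    Returns the copies (sorted by genome position) and per-chromosome sorted
    CpG position arrays.
    """
    spec.validate()
    rng = _as_rng(spec.seed if rng is None else rng)
    chroms = list(spec.chrom_lengths)
    chrom_len = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)

    families, lengths = [], []
    for fam, n in spec.n_copies_per_family.items():
        if n == 0:
            continue
        w = np.asarray(spec.length_distribution[fam], dtype=float)
        w = w / w.sum()
        cls = rng.choice(3, size=n, p=w)
        lo = np.array([r[0] for r in spec.length_ranges])
        hi = np.array([r[1] for r in spec.length_ranges])
        ln = rng.integers(lo[cls], hi[cls] + 1)
        families.extend([fam] * n)
        lengths.extend(ln.tolist())
    families = np.array(families, dtype=object)
    lengths = np.array(lengths, dtype=np.int64)
    n_total = len(lengths)

    copies: list[RepeatCopy] = []
    if n_total:
        placed = False
        for _ in range(50):  # bounded retries on chromosome assignment
            assign = rng.choice(len(chroms), size=n_total, p=chrom_len / chrom_len.sum())
            if all(
                lengths[assign == i].sum() <= chrom_len[i] for i in range(len(chroms))
            ):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place all copies without overlap; enlarge the genome "
                "or reduce copy numbers"
            )
        strands = rng.choice(["+", "-"], size=n_total)
        starts = np.empty(n_total, dtype=np.int64)
        for i, c in enumerate(chroms):
            m = np.flatnonzero(assign == i)
            if not len(m):
                continue
            m = rng.permutation(m)  # random order along the chromosome
            ln = lengths[m]
            free = spec.chrom_lengths[c] - ln.sum()
            gaps = np.sort(rng.integers(0, free + 1, size=len(m)))
            starts[m] = gaps + np.concatenate(([0], np.cumsum(ln[:-1])))
        order = np.lexsort((starts, assign))
        counters: dict[str, int] = {}
        for k in order:
            fam = families[k]
            counters[fam] = counters.get(fam, 0) + 1
            subfam = _draw_subfamily(spec, fam, int(lengths[k]), rng)
            copies.append(
                RepeatCopy(
                    GenomicInterval(
                        chroms[assign[k]],
                        int(starts[k]),
                        int(starts[k] + lengths[k]),
                        str(strands[k]),
                    ),
                    family=fam,
                    subfamily=subfam,
                    copy_id=f"{fam}_{counters[fam]:05d}",
                )
            )

    cpgs = _scatter_cpgs(spec, copies, rng)
    return copies, cpgs


def _draw_subfamily(spec: AgingSimSpec, family: str, length: int, rng) -> str:
    pool = _SUBFAMILY_POOL[family]
    if family == "LINE1" and length > 5000:
        if rng.random() < spec.active_fraction_of_long_line1:
            return str(rng.choice(sorted(spec.active_subfamilies)))
    return str(rng.choice(pool))


def _scatter_cpgs(spec: AgingSimSpec, copies, rng) -> dict[str, np.ndarray]:
    per_chrom: dict[str, list[np.ndarray]] = {c: [] for c in spec.chrom_lengths}
    for c, L in spec.chrom_lengths.items():
        n_bg = rng.poisson(spec.cpg_rate_background * L)
        per_chrom[c].append(rng.integers(0, L, size=n_bg))
    for copy in copies:
        # copies are degenerate duplicates of a family consensus: their CpG
        # content tracks length with only modest divergence, not Poisson scatter
        n = int(round(spec.cpg_rate_repeat * copy.length * rng.normal(1.0, spec.cpg_content_cv)))
        if n <= 0:
            continue
        if copy.family == "ERV1":
            n5 = rng.binomial(n, spec.erv1_5prime_cpg_fraction)
            mid = copy.start + copy.length // 2
            if copy.strand == "-":  # 5' half sits at the genomic end
                five = rng.integers(mid, copy.end, size=n5)
                three = rng.integers(copy.start, mid, size=n - n5)
            else:
                five = rng.integers(copy.start, mid, size=n5)
                three = rng.integers(mid, copy.end, size=n - n5)
            pos = np.concatenate([five, three])
        else:
            pos = rng.integers(copy.start, copy.end, size=n)
        per_chrom[copy.chrom].append(pos)
    return {
        c: np.unique(np.concatenate(parts)) if parts else np.array([], dtype=np.int64)
        for c, parts in per_chrom.items()
    }


def _template_cumulative(template: np.ndarray) -> np.ndarray:
    # integral of the step-wise template over [0, 1], for exact segment means
    return np.concatenate(([0.0], np.cumsum(np.asarray(template) / len(template))))


def _segment_template_mean(cum: np.ndarray, u0: float, u1: float) -> float:
    grid = np.linspace(0.0, 1.0, len(cum))
    c0, c1 = np.interp([u0, u1], grid, cum)
    return float((c1 - c0) / (u1 - u0)) if u1 > u0 else float(np.interp(u0, grid, cum))


def generate_baseline_methylome(
    spec: AgingSimSpec,
    copies: list[RepeatCopy],
    rng=None,
) -> tuple[np.ndarray, GroundTruth]:
    """Per-bin baseline methylation in [0, 1] plus planted ground truth.

    Within each copy the family template is stretched over the copy body
    (strand-aware) and scaled by the copy's cluster plateau; bins outside
    copies draw from a low Beta background. Bins partially covered by a copy
    mix the copy and background signals by covered fraction.
    """
    spec.validate()
    rng = _as_rng(spec.seed + 1 if rng is None else rng)
    frame = spec.frame()
    n_bins = frame.n_bins
    w = spec.bin_width
    offsets = frame.offsets
    bin_len = frame.bin_lengths()

    background = rng.beta(*spec.background_beta, size=n_bins)

    # exact cluster-2 fraction per family, sampled without replacement
    cluster: dict[str, int] = {}
    by_family: dict[str, list[int]] = {}
    for i, c in enumerate(copies):
        by_family.setdefault(c.family, []).append(i)
    for fam, idx in by_family.items():
        idx = np.array(idx)
        n2 = int(round(spec.cluster2_fraction * len(idx)))
        low = set(rng.choice(idx, size=n2, replace=False).tolist()) if n2 else set()
        for i in idx:
            cluster[copies[i].copy_id] = 2 if i in low else 1

    cums = {fam: _template_cumulative(tpl) for fam, tpl in spec.family_templates.items()}
    cov = np.zeros(n_bins)
    wsum = np.zeros(n_bins)
    active_ids = set()
    for copy in copies:
        is_active = copy.subfamily in spec.active_subfamilies
        if is_active:
            active_ids.add(copy.copy_id)
        if cluster[copy.copy_id] == 2:
            plateau = spec.plateau_low
        elif is_active:
            plateau = spec.active_plateau
        else:
            plateau = spec.plateau_high
        # copies of a family are not epigenetic clones; spread their plateaus
        plateau = float(np.clip(plateau * rng.uniform(*spec.plateau_jitter), 0.0, 1.0))
        cum = cums[copy.family]
        off = offsets[copy.chrom]
        b0 = copy.start // w
        b1 = (copy.end - 1) // w
        for b in range(b0, b1 + 1):
            gidx = off + b
            gs = max(copy.start, b * w)
            ge = min(copy.end, b * w + int(bin_len[gidx]))
            if ge <= gs:
                continue
            u0 = (gs - copy.start) / copy.length
            u1 = (ge - copy.start) / copy.length
            if copy.strand == "-":
                u0, u1 = 1.0 - u1, 1.0 - u0
            tmean = _segment_template_mean(cum, u0, u1)
            weight = (ge - gs) / bin_len[gidx]
            cov[gidx] += weight
            wsum[gidx] += weight * plateau * tmean

    covc = np.clip(cov, 0.0, 1.0)
    with np.errstate(invalid="ignore"):
        meth = np.where(cov > 1.0, wsum / cov, wsum + (1.0 - covc) * background)
    meth = np.clip(meth, 0.0, 1.0)

    n_high, n_mid, n_low = scale_stratum_sizes(n_bins)
    order = np.arange(n_bins)
    desc = np.lexsort((order, -meth))
    asc = np.lexsort((order, meth))
    stratum = np.full(n_bins, "mid", dtype=object)
    stratum[desc[:n_high]] = "high"
    stratum[asc[:n_low]] = "low"

    truth = GroundTruth(
        cluster=cluster,
        baseline_methylation=meth.copy(),
        stratum=stratum,
        active_copy_ids=frozenset(active_ids),
    )
    return meth, truth


def apply_aging_drift(
    methylome: np.ndarray,
    months_elapsed: float,
    spec: AgingSimSpec,
    tissue: str = "muscle",
) -> np.ndarray:
    """Regression-toward-the-mean drift.

    Bins above the global mean decay as m * (1 - loss)^months; bins below
    relax toward the mean as m + (mean - m) * (1 - (1 - gain)^months). The
    gain process asymptotes at the mean, so drift contracts variance and
    never crosses the mean or leaves [0, 1]. Identity for tissues with drift
    disabled or months_elapsed == 0.
    """
    if months_elapsed < 0:
        raise ValueError("months_elapsed must be >= 0")
    m = np.asarray(methylome, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("methylome values must lie in [0, 1]")
    if not spec.drift_enabled.get(tissue, False) or months_elapsed == 0:
        return m.copy()
    mean = m.mean()
    out = m.copy()
    above = m > mean
    below = m < mean
    out[above] = m[above] * (1.0 - spec.drift_rate_loss) ** months_elapsed
    out[below] = m[below] + (mean - m[below]) * (
        1.0 - (1.0 - spec.drift_rate_gain) ** months_elapsed
    )
    # losses may undershoot the mean for bins barely above it; cap at the mean
    out[above] = np.maximum(out[above], np.minimum(m[above], mean))
    return np.clip(out, 0.0, 1.0)


def simulate_mbd_reads(
    methylome: np.ndarray,
    cpg_per_bin: np.ndarray,
    frame: BinFrame,
    library_size: int,
    nb_dispersion: float,
    seed,
    read_length: int = 100,
    cpg_epsilon: float = 0.1,
) -> ReadTable:
    """Draw MBD-capture-like reads.

    Expected reads per bin are proportional to methylation x (CpG count +
    epsilon), normalized to the library size; realized counts are negative
    binomial with the given size parameter; reads are placed uniformly inside
    their bin with fixed length.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    rng = _as_rng(seed)
    weight = np.asarray(methylome, float) * (np.asarray(cpg_per_bin, float) + cpg_epsilon)
    total = weight.sum()
    if total <= 0:
        raise ValueError("all-zero expected read vector; nothing to sequence")
    mu = weight * (library_size / total)
    k = float(nb_dispersion)
    p = k / (k + mu)
    counts = rng.negative_binomial(k, p)

    bin_chrom = np.concatenate(
        [np.full(n, c, dtype=object) for c, n in frame.n_bins_per_chrom.items()]
    )
    bin_start = np.concatenate(
        [np.arange(n, dtype=np.int64) * frame.bin_width for n in frame.n_bins_per_chrom.values()]
    )
    bin_len = frame.bin_lengths()

    idx = np.repeat(np.arange(frame.n_bins), counts)
    span = np.maximum(bin_len[idx] - read_length, 0)
    offs = rng.integers(0, span + 1)
    starts = bin_start[idx] + offs
    ends = np.minimum(starts + read_length, bin_start[idx] + bin_len[idx])
    return ReadTable(bin_chrom[idx], starts, ends)


def simulate_expression_counts(
    spec: AgingSimSpec,
    copies: list[RepeatCopy],
    cluster: Mapping[str, int],
    seed,
) -> tuple[pd.DataFrame, dict[str, int], dict[str, str]]:
    """Retroelement RNA-seq-like counts across ages with planted two phases.

    Mean expression per copy drops by the early log2 effect at the middle
    age; between the middle and last age it rises by the late effect, in full
    for large (>3 kb) cluster-1 copies and scaled down for the rest. The table
    additionally carries stable background "gene" features: a merged count
    table is what gets normalized in practice, and without a stable majority
    the median-of-ratios factors would absorb the planted global shifts.
    Returns (feature x sample counts, sample -> age group map,
    feature_id -> true phase).
    """
    if len(spec.ages_months) < 3:
        raise ValueError("need at least three ages for two-phase expression")
    if spec.n_replicates_rnaseq < 2:
        raise ValueError("need at least two replicates per age")
    rng = _as_rng(seed)
    early, late = spec.expression_phase_effects
    ages = list(spec.ages_months)
    young, mid_age, old = ages[0], ages[len(ages) // 2], ages[-1]

    gene_ids = [f"gene_{i + 1:05d}" for i in range(spec.n_background_genes)]
    feature_ids = [c.copy_id for c in copies] + gene_ids
    base = rng.lognormal(
        mean=np.log(spec.expression_base_mean),
        sigma=spec.expression_base_sigma,
        size=len(feature_ids),
    )
    large_c1 = np.array(
        [c.length > 3000 and cluster[c.copy_id] == 1 for c in copies]
        + [False] * spec.n_background_genes
    )
    is_retro = np.array([True] * len(copies) + [False] * spec.n_background_genes)
    late_eff = np.where(
        is_retro,
        np.where(large_c1, late, late * spec.expression_late_other_scale),
        0.0,
    )
    early_eff = np.where(is_retro, early, 0.0)
    means = {
        young: base,
        mid_age: base * 2.0**early_eff,
        old: base * 2.0**early_eff * 2.0**late_eff,
    }

    phases = {
        fid: two_phase_classification(
            (means[young][i], means[mid_age][i], means[old][i])
        )
        for i, fid in enumerate(feature_ids)
    }

    k = float(spec.expression_nb_dispersion)
    data, groups = {}, {}
    for age in (young, mid_age, old):
        mu = means[age]
        for r in range(1, spec.n_replicates_rnaseq + 1):
            s = f"m{age}_r{r}"
            data[s] = rng.negative_binomial(k, k / (k + mu))
            groups[s] = age
    table = pd.DataFrame(data, index=feature_ids)
    return table, groups, phases


@dataclass
class SimulatedStudy:
    """Everything one simulated aging study produces, ready for the pipeline."""

    spec: AgingSimSpec
    frame: BinFrame
    copies: list[RepeatCopy]
    cpgs: dict[str, np.ndarray]
    cpg_per_bin: np.ndarray
    truth: GroundTruth
    methylomes: dict[tuple[str, int], np.ndarray]  # (tissue, age) -> per-bin
    reads: dict[tuple[str, int], ReadTable]
    counts: dict[str, BinCountMatrix]  # tissue -> bins x ages
    fpkm: dict[str, NormalizedMethylome]
    expression: pd.DataFrame | None = None
    expression_groups: dict[str, int] | None = None

    def sample_name(self, age: int) -> str:
        return f"m{age}"


def simulate_study(spec: AgingSimSpec, with_expression: bool = True) -> SimulatedStudy:
    """Run the full generative model and quantify it through the real
    counting/normalization pipeline."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4 + 2 * len(spec.tissues) * len(spec.ages_months))]
    frame = spec.frame()

    copies, cpgs = generate_repeat_annotation(spec, rngs[0])
    baseline, truth = generate_baseline_methylome(spec, copies, rngs[1])

    cpg_per_bin = np.zeros(frame.n_bins, dtype=np.int64)
    for chrom, pos in cpgs.items():
        if len(pos):
            idx = frame.bin_index(np.full(len(pos), chrom, dtype=object), pos)
            cpg_per_bin += np.bincount(idx[idx >= 0], minlength=frame.n_bins)

    methylomes, reads, counts, fpkm = {}, {}, {}, {}
    rng_i = 4
    for tissue in spec.tissues:
        per_sample = {}
        for age in spec.ages_months:
            drifted = apply_aging_drift(
                baseline, age - spec.ages_months[0], spec, tissue
            )
            methylomes[(tissue, age)] = drifted
            rt = simulate_mbd_reads(
                drifted,
                cpg_per_bin,
                frame,
                spec.library_size,
                spec.nb_dispersion,
                rngs[rng_i],
                read_length=spec.read_length,
                cpg_epsilon=spec.cpg_epsilon,
            )
            rng_i += 1
            reads[(tissue, age)] = rt
            per_sample[f"m{age}"] = rt
        counts[tissue] = build_count_matrix(per_sample, frame)
        fpkm[tissue] = fpkm_normalize(counts[tissue])

    expression = groups = None
    if with_expression:
        expression, groups, phases = simulate_expression_counts(
            spec, copies, truth.cluster, rngs[2]
        )
        truth.expression_phase = phases

    return SimulatedStudy(
        spec=spec,
        frame=frame,
        copies=copies,
        cpgs=cpgs,
        cpg_per_bin=cpg_per_bin,
        truth=truth,
        methylomes=methylomes,
        reads=reads,
        counts=counts,
        fpkm=fpkm,
        expression=expression,
        expression_groups=groups,
    )
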