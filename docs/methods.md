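# Methods

`redrift` analyzes age-associated DNA-methylation drift at genomic
retroelements from MBD-capture-style sequencing data, together with a
generative model that plants the drift structure so every analysis stage can
be verified against ground truth. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic tests
do and do not show about real data.

## The measurement model

MBD (methyl-CpG-binding-domain) capture enriches methylated DNA fragments;
read depth over a genomic interval is a semiquantitative proxy for its CpG
methylation level. The pipeline therefore works throughout on binned read
counts:

* the genome is tiled with fixed-width bins (default 500 bp; the final bin
  of each chromosome keeps its true, shorter length);
* each read is assigned to exactly one bin by its midpoint
  (floor((start + end)/2)), so integer counts are conserved —
  assigned + unassigned = input reads. Midpoint assignment matches
  single-assignment intersection counting closely at 500-bp bins with
  ~100-bp reads and keeps counts integral; an optional `extend_bp`
  parameter extends reads toward fragment length first (default 0 — the
  upstream protocol does not state fragment extension);
* counts are normalized to FPKM = count / (bin kb × library millions), and
  to log2(FPKM + 1) for distribution summaries and regression. A pseudocount
  is required because most genomic bins have low or zero coverage; 1.0 on
  the FPKM scale is the default throughout and is recorded on the
  `NormalizedMethylome` object.

## Drift statistics

Bins are ranked once by their enrichment in the youngest (2-month) sample —
descending value, ties broken by genomic order so the stratification is a
deterministic partition. The **high** stratum is the top of that ranking,
the **low** stratum the bottom, and the **mid** stratum the remaining bins
whose baseline values are nearest a target level anchored at roughly 10 raw
reads per bin. The genome-scale default sizes (100,000 / 100,000 /
1,048,575 bins; the last figure is treated as an arbitrary default — it
equals 2^20 − 1 and likely reflects a spreadsheet row limit rather than a
designed quantity) are scaled proportionally onto smaller bin frames so
they partition the frame.

Per stratum and older age, the trajectory is the mean (± sd) of
log2((v_age + 1)/(v_baseline + 1)) over the stratum's bins. For reporting,
the mean log2 fold change is converted to a fold magnitude 2^|mean|, with
the direction carried separately; the per-month drift rate is that
magnitude divided by the age in months (the convention behind
"1.38-fold over 20 months ≈ 0.07-fold per month" and "2.6/28 ≈ 0.093").
Inter-age methylome regressions are ordinary least squares of one sample on
another on the log2 scale; Welch's two-sample t test (Welch–Satterthwaite
degrees of freedom) compares strata, with the convention p = 1 for two
zero-variance groups with equal means.

## Meta-profiles and cluster decomposition

Each repeat copy's span is resampled onto 100 equal body segments between
its start and end sites, oriented 5′→3′ (minus-strand rows are reversed).
Segment values are exact length-weighted means of the 500-bp bin track,
computed from the per-chromosome cumulative integral of the track — this
reuses the quantification frame rather than re-counting reads, at the cost
of flattening sub-bin structure in copies shorter than a few bins. Copies
shorter than `min_length` (default: one bp per body bin) are excluded and
counted.

Within a family, copies are split into two clusters with k = 2 k-means
(Lloyd's algorithm, k-means++ seeding, best of 10 restarts, fixed random
state) on the profile rows of the youngest sample only; the assignment is
then frozen and reused across ages, because re-clustering per age would
confound membership changes with methylation changes. Cluster 1 is always
relabeled to the higher-methylation group. Rows are not z-scored — cluster
identity is absolute methylation level, which standardization would erase —
but the recommended input track is log2(FPKM + 1): on raw FPKM rows the
Euclidean metric is dominated by the heavy-tailed 5′-peak columns, and at
500-bp resolution peak height is strongly length-dependent, so k-means
splits long-vs-short rather than methylated-vs-unmethylated copies. The log
scale preserves absolute level while keeping column contributions
commensurate.

Size fractionation uses strict thresholds (>1, >3, >5 kb; nested subsets).
The evolutionarily active LINE1 subfamilies (L1Md_A, L1Md_Gf, L1Md_T) are
separated from the rest by exact subfamily-name matching. CpG-density
profiles count CpG positions (the C on the + strand) in 10 equal,
strand-oriented parts per copy and average per-bp densities across copies;
because the parts are equal-length, pooled per-part counts are
multinomial-uniform under uniform placement, which gives a calibrated
chi-square uniformity test alongside the Spearman rank trend.

## Differential analysis

Size factors use the median-of-ratios estimator: each sample's factor is
the median, over features with nonzero counts in every sample, of that
sample's count divided by the feature's geometric mean. Differential calls
divide counts by the factors, compute log2 fold changes from group means
with a pseudocount of 1, and follow the decision rule fold change > 2 AND
raw p < .05. With replicates, p comes from a two-sample Student t test
(pooled variance) on log2(normalized + 1); BH-adjusted q values are
reported alongside for users who want to tighten, but the significance flag
follows the raw-p rule. The pooled-variance test was chosen over Welch's
because at triplicate group sizes Welch's true size is ≈0.035 rather than
0.05, while the pooled test is exactly calibrated when group variances
match (as they do by construction here). The negative-binomial GLM with
dispersion shrinkage used by full DE frameworks is deliberately **not**
reimplemented; this is a documented simplification, and the
median-of-ratios estimator is cross-checked against an independent
implementation in the test suite. Unreplicated designs (1 vs 1 pooled
libraries) report p = NA and flag on fold change alone.

Strict-overlap feature counting assigns a read to a feature only if the
read interval is wholly contained in it; reads contained in more than one
feature are ambiguous and dropped, reads contained in none are no-feature,
and counted + ambiguous + no-feature always equals the input.

Two-phase trajectory classification takes the (young, mid, old) means,
labels the early delta log2(mid/young) and late delta log2(old/mid) as
−/0/+ against ±0.25 log2 (a quarter-fold minimum effect), and maps the
signs to {down_up, up_down, monotone_up, monotone_down, flat}.

## The generative model

`AgingSimSpec` parameterizes a complete toy study; the defaults define the
study conditions and are not meant to be tuned per run.

**Genome and annotation.** Two 5-Mb chromosomes (20,000 bins at 500 bp)
carry ~2,000 repeat copies of eight families (LINE1, ERV1, ERVK, ERVL,
ERVL-MaLR, SINE B1/B2/B4), placed uniformly at random without overlap
(uniform gap construction), strands Bernoulli(0.5). Copy lengths come from
per-family mixtures over short (<1 kb), mid (1–5 kb), and long (>5 kb)
classes; the modal class is always short — most LINE1 and ERV copies in a
genome are fragments well under 1 kb — with a nonzero long tail for LINE1
and the ERVs. Half of the long (>5 kb) LINE1 copies are labeled with the
active subfamilies.

**CpGs.** CpG positions are scattered at 0.02/bp inside copies and
0.004/bp outside. Per-copy CpG content varies by only ~8% (CV) around the
family rate rather than with Poisson scatter: homologous copies of a family
are degenerate duplicates of one consensus, and Poisson-level content
variation would decouple coverage from methylation in a way real repeat
families do not. ERV1 is the exception family: 75% of its CpGs fall in the
5′ half (strand-aware), planting the 5′-biased density the decile profile
must detect.

**Baseline methylome.** Each family has a body-methylation template over
100 body bins in [0, 1]: ERV1 strong 5′ LTR / weak 3′ LTR; ERVK peaks at
both ends with the 5′ one stronger; ERVL the mirror of ERV1; LINE1 a single
5′ UTR peak; SINEs and MaLR flat plateaus. The template is stretched over
the copy body (strand-aware), scaled by the copy's cluster plateau:
cluster 1 (high) 0.8, cluster 2 (low) 0.2, active-subfamily cluster-1
copies 0.95. A fraction `cluster2_fraction` = 0.2 of each family is
assigned to cluster 2 (within the 10–30% range such low-methylation
subpopulations occupy). Every copy's plateau is additionally jittered by
U(0.75, 1.15): copies are not epigenetic clones, and — numerically — some
true spread at the top of the ranking is needed so that top-stratum
selection is driven by signal rather than by measurement noise (see
*Selection regression* below). Bins outside copies draw from Beta(2, 18)
(mean 0.1); partially covered bins mix copy and background signal by
covered fraction.

**Drift.** Aging drift acts on bins (so genic/background regions drift
too), relative to the global mean methylation of the baseline: bins above
the mean decay multiplicatively, m′ = m(1 − r_loss)^months, and bins below
relax toward the mean, m′ = m + (mean − m)(1 − (1 − r_gain)^months). The
gain process asymptotes at the mean rather than growing without bound, so
drift contracts variance, never crosses the mean, and never leaves [0, 1] —
the "regression toward the mean" contract (|m′ − mean| ≤ |m − mean|,
monotone in months) holds exactly and is property-tested. Defaults
r_loss = 0.0175/month and r_gain = 0.012/month give a cumulative high-bin
log2 change of ≈ −0.46 (≈1.38-fold) by the 20-month timepoint. The control
tissue has drift disabled and is otherwise identical. No quantitative drift
law is established for this system; the exponential form is an
implementation choice, and both rates are configuration, not constants.

**Reads.** Expected reads per bin are proportional to
methylation × (CpG count + 0.1), normalized to the library size; realized
counts are negative binomial (size parameter = dispersion), and reads of
fixed 100-bp length are placed uniformly inside their bin. One pooled
library per age per tissue (the study design pools three animals per age
for capture sequencing), three replicates per age for RNA-seq.

**Expression.** Retroelement features start at lognormal baseline means
(median 100, σ = 0.5); at the middle age all retroelement means shift down
by the early effect (−1 log2); between the middle and last age they shift
up by the late effect (+1.5 log2) — in full for large (>3 kb) cluster-1
copies, at half strength for the rest, so derepression is global but
concentrated where demethylation is. The table also carries 4,000 stable
background gene features. The genes are not decoration: median-of-ratios
normalization of a retroelement-only table would absorb a planted *global*
shift entirely (every feature moves, so the factors move with them), which
is exactly what happens to real data unless the merged count table is
anchored by a stable gene majority. Counts are negative binomial with size
50 per replicate.

### Selection regression and the noise settings

Stratifying bins on a noisy baseline and then measuring fold change against
that same baseline produces a statistical regression artifact: top-ranked
bins are partly selected for upward noise and revert downward even with
zero planted drift. The artifact scales with the measurement CV at the
stratum boundary relative to the true signal spread there. The default
depth (1.44M reads per library, ~72 per bin) and near-Poisson library noise
(NB size 1000) keep this artifact in the non-drifting control at
|mean log2 FC| ≈ 0.02 — comfortably inside the planted-zero band of 0.05 —
while the per-copy plateau jitter supplies true spread at the boundary.
This is the main reason the defaults are deeper than a naive scale-down of
the study's sequencing depth; at ~12 reads per bin the control would show
an apparent drift of ≈0.13 log2 units that is pure selection noise. The
same artifact exists in real ranked-strata analyses and is worth keeping in
mind when interpreting small stratified fold changes.

## What the synthetic tests show — and what they do not

Passing tests demonstrate that every stage recovers what the generator
plants under the stated noise model: drift signs and acceleration in
≥19/20 seeds, variance contraction and slope flattening, cluster recovery
(ARI ≥ 0.9) with loss-of-methylation in cluster 1 and gain in cluster 2,
stronger loss in large copies and active LINE1 subfamilies, the ERV1 CpG
bias, calibrated type-I error, and ≥80% two-phase sensitivity. They do not
show that real MBD-seq data satisfies the model's assumptions: real
capture efficiency varies with CpG density nonlinearly, fragment sizes and
mappability are not modeled, repeat copies are not independent (nested and
truncated insertions share sequence), bisulfite-resolution methylation is
not simulated, and tissue differences are reduced to a single drift switch.
Genome-scale results on real accessions are not reproducible at this desk
scale; the synthetic study is a correctness harness, not a power analysis.

## Numerical choices and degenerate inputs

* Ranking ties break by genomic order everywhere; stratification uses a
  single descending ranking so strata partition even under massive ties.
* k-means with identical rows degrades to a single effective cluster with a
  warning; empty clusters yield NaN profiles with a warning.
* Zero-variance t-test groups with equal means return p = 1 by convention.
* The fold-change histogram counts values outside the edges in explicit
  under/overflow buckets so totals always reconcile.
* bedGraph values are written with 6 significant digits; round-trips are
  exact to 1e−5 relative.
* repeatMasker `.out` coordinates (1-based inclusive) are converted to the
  package-wide 0-based half-open convention on read; unknown repeat classes
  map to family "other" with a logged warning, via an editable mapping
  table (mouse B1/B2/B4 are taken from repFamily directly — no Alu
  aliasing is assumed).
* Problem sizes in tests and the acceptance script (20,000 bins, ~2,000
  copies, 20-seed sweeps) are the package's default study conditions,
  chosen to make the full pipeline cheap enough to re-run from scratch on
  one CPU.

## Interfaces

The package is organised as an analysis project: the numbered scripts under
`analysis/` are the drivers (simulate, quantify, drift, meta-profiles,
expression), each a thin narrative over the library modules in
`src/redrift/`, writing tables under `results/`. Parameterization is the
`AgingSimSpec` dataclass rather than a config-file dialect; programmatic
use goes through the functions re-exported at the package root. SAM input
is supported only by a thin reducer to read intervals (pysam, optional
extra); BAM/CRAM, bigWig writing, and paired-end fragment reconstruction
are out of scope.
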