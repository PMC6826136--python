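# redrift

Age-associated DNA-methylation drift at genomic retroelements, measured
from MBD-capture-style sequencing data — with a ground-truth aging
simulator so the whole pipeline is verifiable without external downloads.

## The problem

In aging skeletal muscle, DNA methylation at repeat elements does not
simply erode. Within each retroelement family (LINE1, ERV1/K/L, SINE
B1/B2/B4), heavily methylated copies lose methylation while weakly
methylated copies gain it — a bidirectional drift, "regression toward the
mean", that contracts the methylome's variance and blunts the sharp
family-specific methylation patterns laid down during development. The
drift accelerates with age, is absent in a control tissue (T cells), is
strongest in large (>5 kb) and evolutionarily active copies, and is
mirrored by a two-phase expression trajectory: global retroelement
repression in early aging, derepression late.

`redrift` is for computational biologists who want to measure this drift
structure in binned enrichment data (MBD-seq, MeDIP-like) and for method
developers who need a planted-truth test bed for ranked-strata drift
statistics, meta-profile clustering, and retroelement differential
expression.

## What it computes

With read depth in 500-bp bins as the methylation proxy
(FPKM = count / (bin kb × library millions)):

* **Drift trajectories** — bins ranked by baseline (2-m) enrichment into
  high / mid (≈10-read) / low strata; per stratum and age the mean
  log2((v_age + 1)/(v_2m + 1)); fold magnitude 2^|mean|; per-month rate =
  fold / months. A 1.38-fold cumulative change by 20 months is
  1.38/20 ≈ **0.069-fold per month**; 2.6-fold by 28 months is **0.093**.
* **Inter-age regression** — OLS of one age on another on the log2 scale;
  drift flattens the slope.
* **Meta-profiles** — copies × 100 body bins (5′→3′, strand-aware, exact
  length-weighted resampling of the bin track); k = 2 k-means splits each
  family into a high- (cluster 1) and low-methylation (cluster 2) group,
  assigned on the youngest sample and frozen across ages; size fractions
  (>1/>3/>5 kb), active-vs-rest LINE1 subfamilies, CpG-density deciles.
* **Differential features** — median-of-ratios size factors; fold
  change > 2 AND p < .05 (Student t on log2 normalized counts, BH q
  reported alongside); strict-overlap (containment) feature counting;
  two-phase trajectory classification (down_up / up_down / monotone / flat).
* **A generative model** (`AgingSimSpec`, `simulate_study`) planting all of
  the above: family body-templates, two-cluster copies, exponential
  regression-toward-the-mean drift, a non-drifting control tissue,
  negative-binomial MBD reads, and repress-then-derepress expression.

## Worked example

```python
import redrift as rd

study = rd.simulate_study(rd.AgingSimSpec(seed=0))   # ~2,000 copies, 20,000 bins
fp = study.fpkm["muscle"]                            # bins x {m2, m20, m28} FPKM

n_high, n_mid, n_low = rd.scale_stratum_sizes(study.frame.n_bins)
mid = rd.fpkm_for_count(10, 500, study.spec.library_size)
strata = rd.stratify_by_baseline(fp, "m2", n_high, n_mid, n_low, mid)
for t in rd.stratum_trajectory(fp, strata, "m2", ["m20", "m28"],
                               months={"m20": 20, "m28": 28}):
    print(t.to_frame().round(3))
```

The analysis drivers under `analysis/` run the same computations
end-to-end and narrate the result. On the default study they print:

```
muscle stratum trajectories (mean log2 FC vs 2 m):
stratum sample  mean_log2_fc  fold_magnitude  rate_per_month
   high    m20        -0.147           1.107           0.055
   high    m28        -0.223           1.167           0.042
    low    m20         0.480           1.394           0.070
    low    m28         0.649           1.569           0.056
```

— the high stratum loses methylation and the low stratum gains it, both
accelerating with age (the control tissue's trajectories stay within
±0.02), the 28-m log2 variance contracts (6.06 → 4.47), cluster 1 shows
loss and cluster 2 gain in every family, >5 kb cluster-1 LINE1 copies drop
~53 FPKM versus ~21 for <1 kb copies, and the expression stage recovers the
planted repress-then-derepress trajectory for ~90% of copies:

```
2 m -> 20 m: 195 / 2000 retroelements differential (fold > 2, p < .05); 0 up, 195 down
20 m -> 28 m: 225 / 2000 retroelements differential (fold > 2, p < .05); 225 up, 0 down
```

Run them in order:

```bash
python analysis/01_simulate_dataset.py      # genome, methylomes, reads, counts
python analysis/02_bin_quantification.py    # FPKM + distribution summaries
python analysis/03_drift_trajectories.py    # strata, rates, regression, histograms
python analysis/04_metaprofiles.py          # clusters, size fractions, CpG deciles
python analysis/05_retroelement_expression.py  # size factors, DE, two-phase classes
```

Tables land under `results/`.

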