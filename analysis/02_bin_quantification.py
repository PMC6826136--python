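#!/usr/bin/env python
"""Quantify the simulated MBD libraries in 500-bp bins and summarize.

Counts reads by midpoint into the genome tiling, normalizes to FPKM and
log2(FPKM + 1), and writes per-sample distribution summaries. The telling
readout is the variance column: the 28-m drifted muscle methylome is tighter
than the 2-m one (regression toward the mean), while the control tissue
barely moves.
"""

from pathlib import Path

import pandas as pd

from redrift import AgingSimSpec, distribution_summary, log2_with_pseudocount, simulate_study

OUT = Path(__file__).resolve().parent.parent / "results" / "quantification"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = simulate_study(AgingSimSpec(seed=0), with_expression=False)

    summaries = []
    for tissue, fp in study.fpkm.items():
        s = distribution_summary(log2_with_pseudocount(fp))
        s.insert(0, "tissue", tissue)
        summaries.append(s)
        pd.DataFrame(
            fp.values, columns=fp.sample_ids
        ).to_csv(OUT / f"fpkm_{tissue}.tsv", sep="\t", index=False)
    summary = pd.concat(summaries)
    summary.to_csv(OUT / "distribution_summary.tsv", sep="\t")

    print(summary.round(3))
    mv = summary[summary.tissue == "muscle"]["variance"]
    print(
        f"\nmuscle log2 variance {mv.iloc[0]:.2f} (2 m) -> {mv.iloc[-1]:.2f} (28 m): "
        f"{'contracted' if mv.iloc[-1] < mv.iloc[0] else 'NOT contracted'}"
    )


if __name__ == "__main__":
    main()
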