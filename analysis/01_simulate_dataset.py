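#!/usr/bin/env python
"""Generate the default synthetic aging study and write its raw artifacts.

A 2 x 5 Mb toy genome is populated with ~2,000 retroelement copies, a
baseline methylome with family-specific body templates and a two-cluster
copy structure, then aged to 20 and 28 months under regression-toward-the-
mean drift (muscle) or no drift (T-cell control), and sequenced into
MBD-capture-like reads and RNA-seq-like counts.

Outputs under results/simulation/: repeat annotation (BED6+2), chrom sizes,
true methylomes (bedGraph), per-tissue bin count tables (TSV), expression
counts (TSV), and the planted ground truth (TSV).
"""

from pathlib import Path

import pandas as pd

from redrift import AgingSimSpec, simulate_study, write_bedgraph, write_repeat_bed

OUT = Path(__file__).resolve().parent.parent / "results" / "simulation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = AgingSimSpec(seed=0)
    study = simulate_study(spec)

    write_repeat_bed(study.copies, OUT / "repeats.bed")
    (OUT / "genome.chrom.sizes").write_text(
        "".join(f"{c}\t{L}\n" for c, L in spec.chrom_lengths.items())
    )
    bins = study.frame.intervals()
    for (tissue, age), meth in study.methylomes.items():
        write_bedgraph(bins, meth, OUT / f"true_methylome_{tissue}_m{age}.bedGraph")
    for tissue, matrix in study.counts.items():
        matrix.to_frame().to_csv(OUT / f"bin_counts_{tissue}.tsv", sep="\t", index=False)
    study.expression.to_csv(OUT / "expression_counts.tsv", sep="\t")

    truth = pd.DataFrame(
        {
            "copy_id": [c.copy_id for c in study.copies],
            "family": [c.family for c in study.copies],
            "subfamily": [c.subfamily for c in study.copies],
            "length": [c.length for c in study.copies],
            "cluster": [study.truth.cluster[c.copy_id] for c in study.copies],
            "expression_phase": [
                study.truth.expression_phase.get(c.copy_id, "") for c in study.copies
            ],
        }
    )
    truth.to_csv(OUT / "ground_truth_copies.tsv", sep="\t", index=False)

    n_long = sum(c.length > 5000 for c in study.copies)
    print(f"simulated {len(study.copies)} copies on {study.frame.n_bins} bins")
    print(f"  >5 kb copies: {n_long}; CpGs: {sum(len(v) for v in study.cpgs.values())}")
    print(f"  reads per sample: {spec.library_size}; outputs in {OUT}")


if __name__ == "__main__":
    main()
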