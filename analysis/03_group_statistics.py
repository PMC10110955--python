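#!/usr/bin/env python
"""Genotype and treatment statistics on the measured cohort.

Compares WKY vs SHR evoked kinetics (Mann-Whitney with median 95% CIs and
25/75 percentiles, Kolmogorov-Smirnov on the amplitude ECDF), runs the
genotype x treatment two-way ANOVA across the hexamethonium-style block,
and summarizes the percent-remaining comparison. Writes tidy tables under
results/stats/ and prints the headline numbers.
"""

from pathlib import Path

import pandas as pd

from gpcal import io
from gpcal.pipeline import compare_genotypes, factorial_block_table
from gpcal.stats import compare_unpaired

IN = Path("results/cohort")
OUT = Path("results/stats")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    kinetics = pd.read_csv(IN / "kinetics.csv")
    block = pd.read_csv(IN / "block.csv")

    comparisons = compare_genotypes(kinetics, epoch="baseline")
    comparisons.to_csv(OUT / "comparisons.csv", index=False, float_format=io.FLOAT_FORMAT)
    anova = factorial_block_table(kinetics)
    anova.to_csv(OUT / "anova.csv", index=False, float_format=io.FLOAT_FORMAT)

    pct = compare_unpaired(
        block.loc[block["genotype"] == "SHR", "pct_amplitude_remaining"].to_numpy(),
        block.loc[block["genotype"] == "WKY", "pct_amplitude_remaining"].to_numpy(),
        labels=("SHR", "WKY"), metric="pct_amplitude_remaining",
    )

    print("baseline genotype comparisons (cells as units):")
    for row in comparisons.itertuples():
        print(f"  {row.metric:20s} {row.test:18s} p={row.p_value:.4g}  "
              f"{row.group_a} median {row.median_a:.4g} ({row.ci_low_a:.4g}-{row.ci_high_a:.4g}) "
              f"vs {row.group_b} median {row.median_b:.4g} ({row.ci_low_b:.4g}-{row.ci_high_b:.4g})")
    print("genotype x treatment two-way ANOVA:")
    for row in anova.itertuples():
        print(f"  {row.metric:20s} {row.effect:28s} F={row.F:8.2f}  p={row.p_value:.3g}")
    shr, wky = pct.summaries["SHR"], pct.summaries["WKY"]
    print(f"% amplitude remaining under block: SHR median {shr['median']:.1f} "
          f"vs WKY {wky['median']:.1f} (Mann-Whitney p={pct.p_value:.3f})")
    print(f"tables -> {OUT}")


if __name__ == "__main__":
    main()
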