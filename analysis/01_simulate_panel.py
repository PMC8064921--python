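#!/usr/bin/env python
"""Generate the synthetic RIL field study.

383 recombinant inbred lines from 32 families, genotyped at 3,000 SNPs,
planted in three environments in an alpha-lattice design (2 replications x
32 incomplete blocks) with ~4% of plots discarded for emergence problems.
Writes the raw study tables under results/study/.
"""

from pathlib import Path

import pandas as pd

from yieldpath.pipeline import PipelineConfig, stage_simulate

OUT = Path("results/study")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig(seed=1, outdir=str(OUT))
    snps, trial = stage_simulate(config)

    trial.plots_frame().to_csv(OUT / "plots.csv", index=False)
    trial.cc_frame().to_csv(OUT / "cc.csv", index=False)
    trial.biomass_frame().to_csv(OUT / "biomass.csv", index=False)
    trial.weather.to_csv(OUT / "weather.csv", index=False)
    pd.DataFrame(snps.genotypes, index=snps.line_ids).rename_axis("ril").to_csv(
        OUT / "snps.csv"
    )
    trial.truth.breeding_values.rename_axis("ril").to_csv(OUT / "truth_bv.csv")
    trial.truth.gxe_slopes.rename_axis("ril").to_csv(OUT / "truth_gxe.csv")

    plots = trial.plots_frame()
    print(f"panel: {plots['ril'].nunique()} lines, "
          f"{len(plots)} plots across {plots['env'].nunique()} environments "
          f"(dropped {3 * 2 * config.n_lines - len(plots)} plots)")
    print(f"grain yield mean by environment (kg/ha):\n"
          f"{plots.groupby('env')['grain_yield'].mean().round(0)}")


if __name__ == "__main__":
    main()
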