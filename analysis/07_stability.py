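#!/usr/bin/env python
"""Environmental stability of the yield efficiencies.

Finlay-Wilkinson joint regression per trait on plot values corrected for
replication and incomplete block, slope-based stability typing, and
cross-environment Kendall rank correlations of the per-environment BLUEs.
Writes fw_slopes.csv, stability_summary.csv, tau_{trait}.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from yieldpath.pipeline import STABILITY_TRAITS, stage_stability

OUT = Path("results/study")


def main() -> None:
    traits_plot = pd.read_csv(OUT / "traits_plot.csv")
    blues_by_env = {
        p.stem.split("_", 1)[1]: pd.read_csv(p, index_col=0)
        for p in sorted(OUT.glob("blues_*.csv"))
    }
    fw_results, summary, taus = stage_stability(
        traits_plot, blues_by_env, STABILITY_TRAITS
    )
    slopes = pd.DataFrame({t: res[0].slopes for t, res in fw_results.items()})
    slopes.rename_axis("ril").to_csv(OUT / "fw_slopes.csv")
    summary.to_csv(OUT / "stability_summary.csv", index=False)
    for trait, tau in taus.items():
        tau.rename_axis("env").to_csv(OUT / f"tau_{trait}.csv")

    print("Finlay-Wilkinson slope dispersion (IQR / min / max):")
    print(summary.set_index("trait")[["iqr", "min", "max"]].round(2))
    truth_path = OUT / "truth_gxe.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, index_col=0)["gxe_slope"]
        shared = slopes.index.intersection(truth.index)
        r = np.corrcoef(slopes.loc[shared, "GY"], truth.loc[shared])[0, 1]
        print(f"grain-yield slopes vs generating sensitivities: r = {r:.2f}")
    print("cross-environment Kendall tau (grain yield):")
    print(taus["GY"].round(2))


if __name__ == "__main__":
    main()
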