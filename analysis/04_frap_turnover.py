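#!/usr/bin/env python
"""FRAP turnover analysis: generate bleach cohorts per regime, fit single-
exponential recoveries, and relate nonmobile (stable) fractions to junction
shrinkage.

Writes results/frap_fits_<regime>.csv and results/frap_summary.csv.
"""

from pathlib import Path

import pandas as pd

from pcpdyn.frap_turnover import turnover_vs_behavior
from pcpdyn.presets import PRESET_NAMES, load_preset
from pcpdyn.synthetic_tissue import generate_frap_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 1
N_RECORDS = 30


def main() -> None:
    rows = []
    for preset in PRESET_NAMES:
        cfg = load_preset(preset, seed=SEED)
        records, _ = generate_frap_cohort(cfg, n_records=N_RECORDS)
        res = turnover_vs_behavior(records)
        res.table.to_csv(ROOT / "results" / f"frap_fits_{preset}.csv", index=False)
        by_class = res.table.groupby("shrink_class")["nonmobile_fraction"].mean()
        rows.append(
            {
                "regime": preset,
                "n_records": len(records),
                "nonmobile_shrinking": by_class.get("shrinking"),
                "nonmobile_nonshrinking": by_class.get("nonshrinking"),
                "slope_per_um": res.regression_slope,
                "spearman_rho": res.spearman_rho,
                "spearman_p": res.spearman_p,
            }
        )
        print(
            f"{preset:13s} stable fraction: shrinking = "
            f"{by_class.get('shrinking', float('nan')):.2f}, nonshrinking = "
            f"{by_class.get('nonshrinking', float('nan')):.2f}, "
            f"rho(dL, nonmobile) = {res.spearman_rho:+.2f} (p = {res.spearman_p:.2g})"
        )
    out = ROOT / "results" / "frap_summary.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"\nwrote {out}")
    print("finding: shrinking junctions carry a higher stable (nonmobile) fraction,")
    print("and the stable fraction scales with how much the junction contracted.")


if __name__ == "__main__":
    main()
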