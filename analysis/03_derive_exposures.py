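#!/usr/bin/env python
"""Exposure metrics, visit-to-visit variability, and the outcome-oriented cutoff.

On cohort A (CES-D-8, seed 1): derives CumDS/CumADS/burden/duration/slope/
pattern per participant, fits the VIM calibration (beta from ln SD ~ ln mean),
and searches the maximally selected log-rank cutoff on baseline scores.
Writes the exposure summary, the VIM calibration, and the cutpoint audit
grid to results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import cumdep as cd

RESULTS = Path("results")


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    cfg = cd.cohort_preset("cesd8", n_participants=2000, seed=1,
                           true_loghr={"cumds": float(np.log(1.06))})
    cohort = cd.simulate_cohort(cfg)
    cutoff = cfg.scale.high_threshold

    ex = cd.derive_exposures(cohort.panel, cutoff)
    summary = ex[["cumds", "cumads", "burden_value", "duration_years",
                  "slope"]].describe().T.round(3)
    summary.to_csv(RESULTS / "exposure_summary.csv")

    stats, calib = cd.add_variability(cohort.panel)
    pd.DataFrame([{
        "beta": round(calib.beta, 4), "intercept": round(calib.intercept, 4),
        "n_used": calib.n_used, "n_excluded": calib.n_excluded,
    }]).to_csv(RESULTS / "vim_calibration.csv", index=False)

    base = cohort.panel[cohort.panel["wave"] == 1].set_index("id")
    parts = cohort.participants
    res = cd.optimal_cutoff(base.loc[parts["id"], "score"].to_numpy(),
                            parts["time"].to_numpy(),
                            parts["event"].to_numpy())
    res.grid.round(4).to_csv(RESULTS / "cutpoint_grid.csv", index=False)

    print(summary.to_string())
    print(f"\nVIM calibration: beta = {calib.beta:.3f} over {calib.n_used} "
          f"participants ({calib.n_excluded} excluded with sd=0 or mean<=0)")
    print(res.grid.round(3).to_string(index=False))
    print(f"\nFinding: the outcome-oriented search selects baseline score "
          f">= {res.cutoff:g} (log-rank chi-square {res.chi_square:.1f}); "
          f"the screening threshold for this scale is {cutoff}. Pattern "
          f"distribution: "
          f"{ex['pattern'].value_counts(normalize=True).round(2).to_dict()}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
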