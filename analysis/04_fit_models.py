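#!/usr/bin/env python
"""The full inferential ladder on one synthetic cohort.

Runs the end-to-end pipeline (simulate -> classify -> validate -> derive ->
fit M1-M4 on every exposure coding -> spline -> KM) on a 2000-person
CES-D-8 cohort generated with a true per-unit CumDS hazard ratio of 1.06.
Bulky per-stage artifacts go to scratch/; the report tables (hazard-ratio
ladder, spline curve, KM curves) are copied to results/.
"""

import shutil
import sys
from pathlib import Path

import numpy as np

from cumdep.pipeline import RunConfig, run_pipeline

RESULTS = Path("results")
SCRATCH = Path("scratch/pipeline_run")


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    cfg = RunConfig(preset="cesd8", n_participants=2000, seed=1,
                    true_loghr={"cumds": float(np.log(1.06))},
                    outdir=str(SCRATCH))
    result = run_pipeline(cfg)
    for name in ("cox_ladder.csv", "spline_curve.csv", "km.csv",
                 "metadata.json"):
        shutil.copy(result["paths"][name], RESULTS / name)

    t2 = result["ladder"]
    cont = t2[(t2["coding"] == "cumulative") & (t2["model"] == "M4")].iloc[0]
    meta = result["metadata"]
    print(t2[t2["model"] == "M4"].round(3).to_string(index=False))
    print(f"\nFinding: the fully adjusted per-unit CumDS hazard ratio is "
          f"{cont['hr']:.3f} (95% CI {cont['ci_lower']:.3f}-"
          f"{cont['ci_upper']:.3f}) against a generating truth of 1.06, "
          f"with {meta['events']} events among {meta['n_analytic']} "
          f"analytic participants. The BIC-selected spline used "
          f"{meta['spline_knots']} knots (p_nonlinear = "
          f"{meta['spline_p_nonlinear']:.3f}, consistent with the linear "
          f"generating hazard), and the quartile KM curves separate "
          f"(log-rank p = {meta['km_logrank_p']:.2g}).")
    return 0


if __name__ == "__main__":
    sys.exit(main())
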