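#!/usr/bin/env python
"""Algorithmic dementia ascertainment and the sequential exclusion cascade.

Regenerates cohort A (CES-D-8, seed 1), computes education-stratified
baseline cognition norms, classifies probable dementia by the concurrence
rule (any domain >= 1.5 SD below the stratum mean AND >= 1 ADL difficulty,
or self-report), and applies the five-step exclusion cascade. Writes the
per-step exclusion counts and the classification tally to results/.
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
    cohort = cd.simulate_cognition_adl(cd.simulate_cohort(cfg))

    norms = cd.compute_norms(cohort.panel)
    classified = cd.classify_dementia(cohort.panel, norms)
    flat = classified.drop_duplicates("id")
    by_wave = (flat["first_positive_wave"].value_counts().sort_index()
               .rename_axis("first_positive_wave").reset_index(name="n"))
    by_wave.to_csv(RESULTS / "classification_by_wave.csv", index=False)

    report, kept = cd.validate_panel(cohort.panel, cohort.participants,
                                     classified, min_age=50.0)
    report.to_csv(RESULTS / "exclusion_cascade.csv", index=False)

    lagged = cd.lagged_exclusion(classified)
    n_lag = flat["id"].nunique() - lagged["id"].nunique()

    truth = int(cohort.participants["event"].sum())
    found = int(flat["first_positive_wave"].notna().sum())
    print(by_wave.to_string(index=False))
    print(report.to_string(index=False))
    print(f"\nFinding: the classifier recovers {found}/{truth} simulated "
          f"incident cases exactly (zero-noise planting); the cascade "
          f"removes {report['n_removed'].sum()} of {len(cohort.participants)} "
          f"participants, and the lagged analysis would further drop "
          f"{n_lag} wave-2 incident cases.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
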