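"""Visit-to-visit variability (VVV) of symptom scores: SD, CV and VIM.

Per-person dispersion across waves is summarised three ways: the sample
standard deviation (SD, n-1 denominator), the coefficient of variation
(CV = SD / mean, defined only for positive means), and the variation
independent of the mean, ``VIM = 100 * SD / mean**beta``, where beta is the
cohort-level OLS slope of ln(SD) on ln(mean). By construction VIM is
uncorrelated (in log-log OLS terms) with the person mean, so it isolates
fluctuation from level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def per_person_stats(scores) -> tuple[float, float, float]:
    """Mean, sample SD (n-1) and CV across visits.

    CV is NaN when the mean is not positive (undefined; such participants
    are excluded from CV/VIM analyses).
    """
    s = np.asarray(scores, dtype=float)
    s = s[~np.isnan(s)]
    if s.size < 2:
        raise ValueError("need at least 2 non-missing scores")
    mean = float(np.mean(s))
    sd = float(np.std(s, ddof=1))
    cv = sd / mean if mean > 0 else float("nan")
    return mean, sd, cv


@dataclass
class VimCalibration:
    """Cohort-level VIM calibration: ln(SD) = intercept + beta * ln(mean)."""

    beta: float
    intercept: float
    n_used: int
    n_excluded: int = 0


def fit_vim_beta(means, sds) -> VimCalibration:
    """OLS slope of ln(SD) on ln(mean) over calibration-eligible persons.

    Participants with sd = 0 or mean <= 0 are excluded (their logs are
    undefined); the exclusion count is recorded on the calibration.
    """
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    ok = (m > 0) & (s > 0) & np.isfinite(m) & np.isfinite(s)
    n_excl = int(np.size(m) - np.count_nonzero(ok))
    if np.count_nonzero(ok) < 3:
        raise ValueError("need at least 3 participants with sd > 0 and mean > 0")
    lm, ls = np.log(m[ok]), np.log(s[ok])
    if np.ptp(lm) == 0:
        raise ValueError("zero variance in ln(mean); beta undefined")
    beta, intercept = np.polyfit(lm, ls, 1)
    return VimCalibration(beta=float(beta), intercept=float(intercept),
                          n_used=int(np.count_nonzero(ok)), n_excluded=n_excl)


def vim(sd: float, mean: float, calibration: VimCalibration) -> float:
    """Variation independent of the mean: 100 * SD / mean**beta."""
    if not mean > 0:
        raise ValueError("VIM undefined for non-positive mean")
    return 100.0 * sd / mean ** calibration.beta


def add_variability(
    panel: pd.DataFrame,
    id_col: str = "id",
    score_col: str = "score",
) -> tuple[pd.DataFrame, VimCalibration]:
    """Per-participant mean/sd/cv/vim table plus the cohort calibration.

    Participants ineligible for calibration (sd = 0 or mean <= 0) still
    receive SD (and CV where defined) but vim is NaN.
    """
    stats = (
        panel.groupby(id_col)[score_col]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    stats["cv"] = np.where(stats["mean"] > 0, stats["sd"] / stats["mean"], np.nan)
    calib = fit_vim_beta(stats["mean"], stats["sd"])
    eligible = (stats["mean"] > 0) & (stats["sd"] > 0)
    stats["vim"] = np.nan
    stats.loc[eligible, "vim"] = (
        100.0 * stats.loc[eligible, "sd"] / stats.loc[eligible, "mean"] ** calib.beta
    )
    return stats, calib
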