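"""Cumulative, duration and trajectory exposure metrics for symptom panels.

Given a participant's symptom scores :math:`S_1..S_W` observed at strictly
increasing times :math:`t_1..t_W` (years since the first visit), the module
derives:

* **CumDS** — cumulative depressive symptoms: the trapezoidal time-integral
  of the score trajectory, :math:`\\sum_i \\tfrac{S_i+S_{i+1}}{2}(t_{i+1}-t_i)`
  (units: score-years).
* **CumADS** — cumulative average: CumDS divided by the window length
  :math:`t_W - t_1`; a time-weighted mean score.
* **Cumulative burden** — CumDS centered on a cutoff; its sign classifies
  sustained exposure above vs below the cutoff.
* **Exposure duration** — 2 years per high-score visit among a two-visit
  window (0, 2 or 4 years).
* **Slope** — OLS slope of score on time.
* **Time-course pattern** — the four-way classification of the signs of the
  two successive wave-to-wave changes.

Cohort-level quartile assignment (with per-quartile medians for trend tests)
lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PATTERNS = (
    "decrease_decrease",
    "decrease_increase",
    "increase_decrease",
    "increase_increase",
)


def _validate_series(scores, times) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    if s.shape != t.shape or s.ndim != 1:
        raise ValueError("scores and times must be 1-d arrays of equal length")
    if s.size < 2:
        raise ValueError("at least 2 waves are required")
    if np.any(np.isnan(s)) or np.any(np.isnan(t)):
        raise ValueError("missing scores or times are not allowed")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return s, t


def cumulative_score(scores, times) -> float:
    """Trapezoidal time-integral of the score trajectory (score-years)."""
    s, t = _validate_series(scores, times)
    return float(np.trapezoid(s, t))


def cumulative_average(scores, times) -> float:
    """CumDS divided by the exposure-window length; a time-weighted mean."""
    s, t = _validate_series(scores, times)
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("zero-length exposure window")
    return float(np.trapezoid(s, t) / span)


def cumulative_burden(scores, times, cutoff: float) -> tuple[float, str]:
    """CumDS centered on `cutoff`: value and sign class.

    Returns ``(burden_value, burden_class)`` where
    ``burden_value = CumDS - cutoff * (t_W - t_1)`` and the class is
    ``"nonnegative"`` iff the value is >= 0 (boundary inclusive).
    """
    s, t = _validate_series(scores, times)
    value = float(np.trapezoid(s, t) - cutoff * (t[-1] - t[0]))
    return value, ("nonnegative" if value >= 0 else "negative")


def exposure_duration(
    scores, cutoff: float, window_waves: tuple[int, int] = (0, 1),
    years_per_visit: float = 2.0,
) -> float:
    """Years of high-symptom exposure among a two-visit window.

    Each window visit with score >= cutoff contributes `years_per_visit`
    (the biennial wave spacing), giving 0, 2 or 4 years at the defaults.
    `window_waves` are 0-based wave indices.
    """
    s = np.asarray(scores, dtype=float)
    i, j = window_waves
    try:
        pair = s[[i, j]]
    except IndexError:
        raise ValueError("window waves out of range") from None
    if np.any(np.isnan(pair)):
        raise ValueError("window waves have missing scores")
    return float(years_per_visit * np.count_nonzero(pair >= cutoff))


def symptom_slope(scores, times) -> float:
    """OLS slope of score on time (score units per year)."""
    s, t = _validate_series(scores, times)
    if np.unique(t).size < 2:
        raise ValueError("all times identical")
    return float(np.polyfit(t, s, 1)[0])


def time_course_pattern(s1: float, s2: float, s3: float) -> str:
    """Four-way sign classification of the two successive changes.

    Zero change counts as "decrease" (the scheme has no stable class;
    non-increase is assigned symmetrically to both transitions).
    """
    if any(x is None or np.isnan(x) for x in (s1, s2, s3)):
        raise ValueError("pattern classification requires 3 non-missing scores")
    first = "increase" if s2 - s1 > 0 else "decrease"
    second = "increase" if s3 - s2 > 0 else "decrease"
    return f"{first}_{second}"


@dataclass
class QuartileAssignment:
    """Cohort quartile coding of an exposure variable.

    breakpoints : the 25th/50th/75th percentiles (linear interpolation).
    labels      : per-participant quartile 1-4; a value equal to a
                  breakpoint goes to the lower quartile.
    medians     : per-quartile median of the exposure (used by trend tests).
    """

    breakpoints: np.ndarray
    labels: np.ndarray
    medians: np.ndarray


def assign_quartiles(values) -> QuartileAssignment:
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise ValueError("need at least 8 values for quartiles")
    if np.any(~np.isfinite(v)):
        raise ValueError("values must be finite")
    if np.ptp(v) == 0:
        raise ValueError("degenerate: all values identical, single stratum")
    bps = np.quantile(v, [0.25, 0.5, 0.75])
    labels = 1 + np.searchsorted(bps, v, side="left")
    medians = np.array([
        np.median(v[labels == q]) if np.any(labels == q) else np.nan
        for q in (1, 2, 3, 4)
    ])
    return QuartileAssignment(breakpoints=bps, labels=labels, medians=medians)


def derive_exposures(
    panel: pd.DataFrame,
    cutoff: float,
    duration_window: tuple[int, int] = (0, 1),
    years_per_visit: float = 2.0,
    id_col: str = "id",
    time_col: str = "wave_time",
    score_col: str = "score",
) -> pd.DataFrame:
    """Per-participant exposure profile from a long-format panel.

    Participants with any missing wave score are excluded before metric
    computation (no within-pipeline imputation). Returns one row per
    participant with cumds, cumads, burden_value/class, duration_years,
    slope and (for 3-wave panels) pattern; quartiles are assigned at cohort
    level on cumds and cumads.
    """
    rows = []
    for pid, g in panel.sort_values(time_col).groupby(id_col, sort=True):
        s = g[score_col].to_numpy(dtype=float)
        t = g[time_col].to_numpy(dtype=float)
        if np.any(np.isnan(s)):
            continue
        burden, bclass = cumulative_burden(s, t, cutoff)
        row = {
            id_col: pid,
            "cumds": cumulative_score(s, t),
            "cumads": cumulative_average(s, t),
            "burden_value": burden,
            "burden_class": bclass,
            "duration_years": exposure_duration(s, cutoff, duration_window, years_per_visit),
            "slope": symptom_slope(s, t),
        }
        row["pattern"] = time_course_pattern(*s[:3]) if s.size >= 3 else None
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out) >= 8:
        for var in ("cumds", "cumads"):
            qa = assign_quartiles(out[var].to_numpy())
            out[f"{var}_quartile"] = qa.labels
    out.attrs["cutoff"] = cutoff
    out.attrs["duration_window"] = duration_window
    return out
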