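"""Outcome-oriented dichotomization by maximally selected log-rank statistics.

The screening thresholds of the symptom scales are clinical conventions; the
outcome-oriented alternative picks the score cutoff that best separates
dementia-free survival, i.e. the cutoff maximizing the two-sample log-rank
chi-square over a candidate grid. The log-rank statistic is implemented here
directly (it is the primitive of the search): over ordered distinct event
times, accumulate observed-minus-expected events in one group given the
risk-set sizes, with the hypergeometric variance; the statistic is
``(sum(O-E))^2 / sum(V)``. A k-group generalization backs the Kaplan-Meier
comparisons downstream.

Candidates are restricted so that neither side of the split falls below a
minimum fraction of the sample (default 10%) — the standard guard against
degenerate extreme splits in maximally selected statistics. Ties at the
cutoff go to the high group ("score >= c"); ties between equally good
cutoffs resolve to the smallest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _risk_table(times, events, labels, n_groups):
    """Per distinct event time: events and at-risk counts by group."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(labels, dtype=int)
    event_times = np.unique(t[e == 1])
    d = np.zeros((event_times.size, n_groups))
    n = np.zeros((event_times.size, n_groups))
    for k in range(n_groups):
        tk = t[g == k]
        ek = e[g == k]
        # at risk at time s: t >= s ; events at s among group k
        n[:, k] = (tk[None, :] >= event_times[:, None]).sum(axis=1)
        d[:, k] = ((tk[None, :] == event_times[:, None]) & (ek[None, :] == 1)).sum(axis=1)
    return event_times, d, n


def logrank_statistic(labels, times, events) -> float:
    """Two-sample log-rank chi-square.

    `labels` is a boolean/0-1 array (group membership); `times` follow-up
    times; `events` 0/1 indicators. Raises if either group is empty or no
    events occurred.
    """
    g = np.asarray(labels).astype(int)
    if np.unique(g).size != 2:
        raise ValueError("need exactly two non-empty groups")
    e = np.asarray(events, dtype=int)
    if e.sum() == 0:
        raise ValueError("no events")
    _, d, n = _risk_table(times, e, g, 2)
    dtot = d.sum(axis=1)
    ntot = n.sum(axis=1)
    expected = dtot * n[:, 1] / ntot
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (
            dtot * (n[:, 0] * n[:, 1]) * (ntot - dtot)
            / (ntot**2 * np.maximum(ntot - 1, 1))
        )
    o_minus_e = (d[:, 1] - expected).sum()
    v = var.sum()
    if v <= 0:
        return 0.0
    return float(o_minus_e**2 / v)


def multigroup_logrank(labels, times, events) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi-square, df, p-value)."""
    from scipy import stats

    g = np.asarray(labels)
    groups = np.unique(g)
    k = groups.size
    if k < 2:
        raise ValueError("need at least two groups")
    codes = np.searchsorted(groups, g)
    e = np.asarray(events, dtype=int)
    if e.sum() == 0:
        raise ValueError("no events")
    _, d, n = _risk_table(times, e, codes, k)
    dtot = d.sum(axis=1)
    ntot = n.sum(axis=1)
    # O-E vector and covariance over the first k-1 groups
    oe = np.zeros(k - 1)
    cov = np.zeros((k - 1, k - 1))
    for i in range(k - 1):
        oe[i] = (d[:, i] - dtot * n[:, i] / ntot).sum()
        for j in range(k - 1):
            delta = 1.0 if i == j else 0.0
            cov[i, j] = (
                dtot * (ntot - dtot) / np.maximum(ntot - 1, 1)
                * (n[:, i] / ntot) * (delta - n[:, j] / ntot)
            ).sum()
    chi2 = float(oe @ np.linalg.solve(cov, oe))
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def candidate_cutoffs(scores, min_group_fraction: float = 0.10) -> np.ndarray:
    """Distinct observed values c with both sides of 'score >= c' populated.

    A candidate must leave both the low (< c) and high (>= c) group with at
    least `min_group_fraction` of the sample.
    """
    if not 0 < min_group_fraction < 0.5:
        raise ValueError("min_group_fraction must be in (0, 0.5)")
    s = np.asarray(scores, dtype=float)
    if np.any(~np.isfinite(s)):
        raise ValueError("scores must be finite")
    n = s.size
    out = []
    for c in np.unique(s):
        n_high = int(np.count_nonzero(s >= c))
        n_low = n - n_high
        if min(n_low, n_high) >= min_group_fraction * n:
            out.append(c)
    if not out:
        raise ValueError("no candidate cutoff satisfies the group-size constraint")
    return np.asarray(out)


@dataclass
class CutpointResult:
    """The maximizing cutoff with its full audit grid."""

    cutoff: float
    chi_square: float
    grid: pd.DataFrame = field(repr=False)
    min_group_fraction: float = 0.10


def optimal_cutoff(
    scores, times, events, min_group_fraction: float = 0.10, grid=None
) -> CutpointResult:
    """Maximally selected log-rank cutoff over the candidate grid.

    Evaluates the two-sample log-rank chi-square at every candidate split
    "score >= c" and returns the maximizer (smallest cutoff on ties) with
    the grid retained for audit.
    """
    s = np.asarray(scores, dtype=float)
    cands = np.asarray(grid, dtype=float) if grid is not None else None
    if cands is None:
        cands = candidate_cutoffs(s, min_group_fraction)
    rows = []
    for c in cands:
        high = s >= c
        n_high = int(high.sum())
        n_low = int(s.size - n_high)
        if n_low == 0 or n_high == 0:
            continue
        stat = logrank_statistic(high, times, events)
        rows.append({"cutoff": float(c), "statistic": stat,
                     "n_low": n_low, "n_high": n_high})
    if not rows:
        raise ValueError("no evaluable candidate cutoffs")
    grid_df = pd.DataFrame(rows)
    best = grid_df.sort_values(["statistic", "cutoff"], ascending=[False, True]).iloc[0]
    return CutpointResult(
        cutoff=float(best["cutoff"]),
        chi_square=float(best["statistic"]),
        grid=grid_df,
        min_group_fraction=min_group_fraction,
    )
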