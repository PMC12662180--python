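"""Harmonized algorithmic dementia ascertainment.

Probable dementia is classified per wave either by the *concurrence* rule —
any cognitive domain score at least 1.5 SD below the education-stratified
population mean (boundary inclusive) together with difficulty in at least
one activity of daily living — or, HRS-style, by a cognition *summary score*
(0-27) at or below a cut (default 6). A self-reported physician diagnosis
at any wave also confers positivity under the "either" basis. Once
positive, status is absorbing across subsequent waves.

Norms (per education stratum x cognitive domain mean and SD) are computed
from the baseline wave so that incident decline does not contaminate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_DOMAINS = ("memory", "orientation", "executive")


@dataclass
class CohortNorms:
    """Education-stratified baseline norms: (stratum, domain) -> (mean, sd)."""

    table: dict[tuple[object, str], tuple[float, float]] = field(default_factory=dict)
    domains: tuple[str, ...] = DEFAULT_DOMAINS

    def get(self, stratum, domain) -> tuple[float, float]:
        try:
            return self.table[(stratum, domain)]
        except KeyError:
            raise KeyError(f"no norms for stratum {stratum!r}, domain {domain!r}")


def compute_norms(
    panel: pd.DataFrame,
    domains=DEFAULT_DOMAINS,
    education_col: str = "education",
    wave_col: str = "wave",
    baseline_wave: int = 1,
) -> CohortNorms:
    """Per-stratum, per-domain mean and sample SD from baseline-wave scores."""
    base = panel[panel[wave_col] == baseline_wave]
    norms = CohortNorms(domains=tuple(domains))
    for stratum, g in base.groupby(education_col):
        for dom in domains:
            vals = g[dom].dropna().to_numpy(dtype=float)
            if vals.size < 2:
                raise ValueError(
                    f"stratum {stratum!r} has fewer than 2 participants for {dom!r}"
                )
            sd = float(np.std(vals, ddof=1))
            if sd == 0:
                raise ValueError(f"zero SD in stratum {stratum!r}, domain {dom!r}")
            norms.table[(stratum, dom)] = (float(np.mean(vals)), sd)
    return norms


def cognitive_impairment(domain_scores: dict, norms: CohortNorms, stratum) -> bool:
    """True iff any domain score is >= 1.5 SD below the stratum mean.

    The boundary is inclusive: a score exactly at mean - 1.5 SD is impaired.
    """
    for dom, score in domain_scores.items():
        if score is None or (isinstance(score, float) and np.isnan(score)):
            continue
        mean, sd = norms.get(stratum, dom)
        if score <= mean - 1.5 * sd:
            return True
    return False


def functional_impairment(adl_difficulties: int) -> bool:
    """True iff the participant reports difficulty with >= 1 ADL."""
    if adl_difficulties < 0:
        raise ValueError("ADL difficulty count must be non-negative")
    return adl_difficulties >= 1


def classify_dementia(
    panel: pd.DataFrame,
    norms: CohortNorms | None = None,
    rule: str = "concurrence",
    summary_cut: int = 6,
    basis: str = "either",
    id_col: str = "id",
    wave_col: str = "wave",
    education_col: str = "education",
    adl_col: str = "adl",
    self_report_col: str = "self_report",
    summary_col: str = "cog_summary",
) -> pd.DataFrame:
    """Per-wave absorbing dementia status for every participant.

    rule="concurrence": positive at the first wave where cognitive and
    functional impairment both hold. rule="summary_score": positive when
    the 0-27 cognition composite is <= `summary_cut`. basis="either" also
    accepts a self-reported physician diagnosis; basis="algorithmic"
    ignores self-report.

    Returns one row per participant-wave with columns `status` (absorbing
    boolean) and, merged per participant, `first_positive_wave`.
    """
    if rule not in ("concurrence", "summary_score"):
        raise ValueError(f"unknown rule {rule!r}")
    if basis not in ("algorithmic", "self_report", "either"):
        raise ValueError(f"unknown basis {basis!r}")
    if rule == "concurrence" and norms is None:
        raise ValueError("concurrence rule requires cohort norms")

    out = []
    for pid, g in panel.sort_values(wave_col).groupby(id_col, sort=True):
        positive = False
        first_wave = None
        for _, row in g.iterrows():
            fired = False
            if basis != "self_report":
                if rule == "concurrence":
                    domains = {d: row[d] for d in norms.domains}
                    fired = cognitive_impairment(
                        domains, norms, row[education_col]
                    ) and functional_impairment(int(row[adl_col]))
                else:
                    comp = row[summary_col]
                    if not np.isnan(comp) and not (0 <= comp <= 27):
                        raise ValueError("summary composite out of range 0-27")
                    fired = bool(comp <= summary_cut)
            if basis != "algorithmic" and bool(row.get(self_report_col, False)):
                fired = True
            if fired and not positive:
                positive = True
                first_wave = int(row[wave_col])
            out.append({id_col: pid, wave_col: int(row[wave_col]), "status": positive})
        for rec in out[-len(g):]:
            rec["first_positive_wave"] = first_wave
    res = pd.DataFrame(out)
    res["basis"] = basis
    return res


def lagged_exclusion(
    classified: pd.DataFrame, id_col: str = "id", lag_wave: int = 2
) -> pd.DataFrame:
    """Drop participants first classified positive at the wave after baseline.

    Removes reverse-causation candidates (prodromal cases incident within
    the first inter-wave interval); all other records pass through
    untouched.
    """
    drop = classified.loc[
        classified["first_positive_wave"] == lag_wave, id_col
    ].unique()
    return classified[~classified[id_col].isin(drop)].copy()


def exclude_baseline_prevalent(
    classified: pd.DataFrame, id_col: str = "id"
) -> pd.DataFrame:
    """Drop participants already positive at wave 1 (prevalent cases)."""
    drop = classified.loc[classified["first_positive_wave"] == 1, id_col].unique()
    return classified[~classified[id_col].isin(drop)].copy()
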