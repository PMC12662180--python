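"""Cox-model inferential ladder for cumulative depression exposures.

Four nested proportional-hazards specifications are used throughout:

* **M1** — unadjusted.
* **M2** — age, gender, marital status, education level, residence.
* **M3** — M2 + smoking status, drinking status, CRP, HbA1c, TC, HDL-C.
* **M4** — M3 + hypertension, diabetes, heart disease, stroke.

Exposures enter continuously, as quartile dummies (with the lowest quartile
as reference), as binary burden / slope codings, duration categories,
trajectory-pattern categories, or per-SD z-scores. Trend tests substitute
each quartile's median exposure as a single continuous covariate.
Dose-response shape is examined with restricted cubic splines whose knot
count is chosen by BIC; Kaplan-Meier curves with k-group log-rank tests
give the absolute-scale companion view. Partial-likelihood maximization is
delegated to lifelines (Efron tie handling); logistic sensitivity fits go
through statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cutpoint import multigroup_logrank

_M2 = ["age", "female", "married", "edu_hs", "edu_college", "urban"]
_M3 = _M2 + ["smoke_former", "smoke_current", "drinking", "crp", "hba1c", "tc", "hdl"]
_M4 = _M3 + ["hypertension", "diabetes", "heart_disease", "stroke"]

COVARIATE_LADDER = {"M1": [], "M2": _M2, "M3": _M3, "M4": _M4}

EXPOSURE_CODINGS = (
    "continuous", "quartile", "burden_binary", "duration_category",
    "slope_binary", "pattern_category", "sd", "cv", "vim", "zscore",
)


@dataclass
class ModelSpec:
    """One rung of the covariate ladder plus exposure-coding metadata."""

    model_id: str = "M4"
    exposure_coding: str = "continuous"
    ties_method: str = "efron"
    time_origin: str = "baseline"

    def __post_init__(self) -> None:
        if self.model_id not in COVARIATE_LADDER:
            raise ValueError(f"unknown model {self.model_id!r}")
        if self.exposure_coding not in EXPOSURE_CODINGS:
            raise ValueError(f"unknown exposure coding {self.exposure_coding!r}")
        if self.ties_method != "efron":
            raise NotImplementedError(
                "only Efron tie handling is available in the fitting backend"
            )
        if self.time_origin not in ("baseline", "exposure_end"):
            raise ValueError(f"unknown time origin {self.time_origin!r}")

    @property
    def covariates(self) -> list[str]:
        return list(COVARIATE_LADDER[self.model_id])


@dataclass
class CoxFit:
    """Coefficient-level inference from a proportional-hazards fit.

    `terms` has one row per model term: coef, se, hr, ci_lower, ci_upper, p.
    """

    terms: pd.DataFrame = field(repr=False)
    log_likelihood: float = float("nan")
    n: int = 0
    n_events: int = 0
    converged: bool = True
    reference: str | None = None

    def hr(self, term: str) -> float:
        return float(self.terms.loc[term, "hr"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.terms.loc[term]
        return float(row["ci_lower"]), float(row["ci_upper"])


def _check_design(df: pd.DataFrame, cols: list[str]) -> None:
    for c in cols:
        v = df[c].to_numpy(dtype=float)
        if np.any(np.isnan(v)):
            raise ValueError(f"covariate {c!r} has missing values")
        if np.ptp(v) == 0:
            raise ValueError(f"covariate {c!r} is constant")


def fit_cox(
    df: pd.DataFrame,
    exposure_cols: list[str] | str,
    spec: ModelSpec | None = None,
    duration_col: str = "time",
    event_col: str = "event",
    strata: str | None = None,
    entry_col: str | None = None,
) -> CoxFit:
    """Maximize the Cox partial likelihood (Efron ties) and summarize terms.

    `exposure_cols` are the exposure design columns (for categorical codings
    the reference level is the omitted dummy); `spec` supplies the covariate
    ladder. `strata` fits separate baseline hazards per group (used for
    pooled per-SD estimates); `entry_col` enables delayed entry (age scale).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if isinstance(exposure_cols, str):
        exposure_cols = [exposure_cols]
    spec = spec or ModelSpec("M1")
    cols = exposure_cols + [c for c in spec.covariates if c not in exposure_cols]
    keep = cols + [duration_col, event_col]
    if strata:
        keep.append(strata)
    if entry_col:
        keep.append(entry_col)
    data = df[keep].dropna()
    n_events = int(data[event_col].sum())
    if n_events == 0:
        raise ValueError("zero events: cannot fit a Cox model")
    _check_design(data, cols)

    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(
                data,
                duration_col=duration_col,
                event_col=event_col,
                strata=strata,
                entry_col=entry_col,
                show_progress=False,
            )
        except ConvergenceError as err:
            raise ValueError(f"Cox model did not converge: {err}") from err
    coefs = cph.params_
    ses = cph.standard_errors_
    z = coefs / ses
    terms = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "hr": np.exp(coefs),
            "ci_lower": np.exp(coefs - 1.96 * ses),
            "ci_upper": np.exp(coefs + 1.96 * ses),
            "p": 2 * sps.norm.sf(np.abs(z)),
        }
    )
    terms.index.name = "term"
    fit = CoxFit(
        terms=terms,
        log_likelihood=float(cph.log_likelihood_),
        n=int(len(data)),
        n_events=n_events,
        converged=converged,
    )
    fit._cov = cph.variance_matrix_  # retained for Wald tests on subsets
    return fit


def wald_test(coefs: np.ndarray, cov: np.ndarray) -> tuple[float, int, float]:
    """Joint Wald chi-square that a coefficient subvector is zero."""
    coefs = np.atleast_1d(np.asarray(coefs, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    chi2 = float(coefs @ np.linalg.solve(cov, coefs))
    df = coefs.size
    return chi2, df, float(sps.chi2.sf(chi2, df))


def trend_test(
    df: pd.DataFrame,
    labels: np.ndarray,
    medians: np.ndarray,
    spec: ModelSpec | None = None,
    duration_col: str = "time",
    event_col: str = "event",
) -> float:
    """Quartile trend test: Wald p of the median-scored exposure.

    Each participant's quartile label is replaced by that quartile's median
    exposure value and the Cox model refit with this single continuous term.
    """
    medians = np.asarray(medians, dtype=float)
    if np.any(~np.isfinite(medians)):
        raise ValueError("degenerate quartiles: missing median")
    scored = medians[np.asarray(labels, dtype=int) - 1]
    work = df.copy()
    work["_trend"] = scored
    fit = fit_cox(work, "_trend", spec, duration_col, event_col)
    return float(fit.terms.loc["_trend", "p"])


# --- restricted cubic splines -------------------------------------------------

KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis, truncated-power form.

    Column 0 is x itself; columns 1..k-2 are the nonlinear terms,
    constrained so the function is linear beyond the boundary knots and
    scaled by the squared knot span for numerical stability.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = t.size
    if k < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")
    norm = (t[-1] - t[0]) ** 2

    def plus3(u):
        return np.where(u > 0, u, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            plus3(x - t[j])
            - plus3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + plus3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


@dataclass
class SplineFit:
    """BIC-selected restricted-cubic-spline dose-response fit."""

    knots: np.ndarray
    n_knots: int
    bic_by_knots: dict[int, float]
    curve: pd.DataFrame = field(repr=False)
    p_overall: float = float("nan")
    p_nonlinear: float = float("nan")
    reference_value: float = float("nan")
    cox: CoxFit | None = None


def rcs_fit(
    df: pd.DataFrame,
    exposure: str,
    spec: ModelSpec | None = None,
    candidate_knots=(3, 4, 5),
    duration_col: str = "time",
    event_col: str = "event",
    reference: float | None = None,
    n_grid: int = 100,
) -> SplineFit:
    """Fit Cox models with 3/4/5-knot restricted cubic splines; pick by BIC.

    Knots sit at the standard quantiles (3: 10/50/90%; 4: 5/35/65/95%;
    5: 5/27.5/50/72.5/95%). BIC = -2 * partial log-likelihood +
    k * ln(events) with k the number of fitted parameters. p_overall tests
    all spline terms jointly; p_nonlinear tests the nonlinear terms only.
    The curve is the fitted log-HR (with pointwise 95% CI) relative to the
    reference exposure value (cohort median unless given).
    """
    x = df[exposure].to_numpy(dtype=float)
    if np.unique(x[~np.isnan(x)]).size < max(candidate_knots):
        raise ValueError("too few distinct exposure values for the spline")
    spec = spec or ModelSpec("M1")

    results = {}
    for k in candidate_knots:
        knots = np.quantile(x[~np.isnan(x)], KNOT_QUANTILES[k])
        if np.any(np.diff(knots) <= 0):
            continue
        basis = rcs_basis(x, knots)
        work = df.copy()
        names = [f"_rcs{j}" for j in range(basis.shape[1])]
        for j, nm in enumerate(names):
            work[nm] = basis[:, j]
        fit = fit_cox(work, names, spec, duration_col, event_col)
        n_params = len(fit.terms)
        bic = -2 * fit.log_likelihood + n_params * np.log(fit.n_events)
        results[k] = (bic, knots, names, fit)
    if not results:
        raise ValueError("no valid knot configuration")

    bics = {k: v[0] for k, v in results.items()}
    best_k = min(bics, key=lambda k: (bics[k], k))
    _, knots, names, fit = results[best_k]

    cov = fit._cov.loc[names, names].to_numpy()
    beta = fit.terms.loc[names, "coef"].to_numpy()
    _, _, p_overall = wald_test(beta, cov)
    if len(names) > 1:
        _, _, p_nonlinear = wald_test(
            beta[1:], cov[1:, 1:]
        )
    else:  # pragma: no cover - 3 knots always yield a nonlinear column
        p_nonlinear = float("nan")

    ref = float(np.median(x)) if reference is None else float(reference)
    grid = np.linspace(np.min(x), np.max(x), n_grid)
    b_grid = rcs_basis(grid, knots)
    b_ref = rcs_basis(np.array([ref]), knots)
    contrast = b_grid - b_ref
    loghr = contrast @ beta
    var = np.einsum("ij,jk,ik->i", contrast, cov, contrast)
    se = np.sqrt(np.maximum(var, 0))
    curve = pd.DataFrame(
        {
            "exposure": grid,
            "loghr": loghr,
            "ci_lower": loghr - 1.96 * se,
            "ci_upper": loghr + 1.96 * se,
        }
    )
    return SplineFit(
        knots=knots,
        n_knots=best_k,
        bic_by_knots=bics,
        curve=curve,
        p_overall=p_overall,
        p_nonlinear=p_nonlinear,
        reference_value=ref,
        cox=fit,
    )


# --- Kaplan-Meier -------------------------------------------------------------

@dataclass
class KMEstimate:
    """Product-limit curves per group with a k-group log-rank comparison."""

    curves: dict[object, pd.DataFrame] = field(repr=False, default_factory=dict)
    logrank_chi2: float = float("nan")
    logrank_df: int = 0
    logrank_p: float = float("nan")


def km_estimate(
    df: pd.DataFrame,
    group_col: str,
    duration_col: str = "time",
    event_col: str = "event",
) -> KMEstimate:
    """Kaplan-Meier survival per group plus the k-group log-rank test."""
    from lifelines import KaplanMeierFitter

    est = KMEstimate()
    for g, sub in df.groupby(group_col):
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col])
        tbl = kmf.event_table
        est.curves[g] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(
                    kmf.survival_function_.index
                ).to_numpy(),
            }
        )
    if df[group_col].nunique() >= 2 and df[event_col].sum() > 0:
        chi2, dfree, p = multigroup_logrank(
            df[group_col].to_numpy(), df[duration_col].to_numpy(),
            df[event_col].to_numpy()
        )
        est.logrank_chi2, est.logrank_df, est.logrank_p = chi2, dfree, p
    return est


# --- subgroup / sensitivity ---------------------------------------------------

def subgroup_analysis(
    df: pd.DataFrame,
    exposure: str,
    subgroup_col: str,
    spec: ModelSpec | None = None,
    duration_col: str = "time",
    event_col: str = "event",
) -> tuple[dict[object, CoxFit], float]:
    """Stratum-specific fits plus an interaction p-value.

    Fits the spec model within each level of `subgroup_col` (strata with
    zero events are skipped) and tests effect homogeneity via a Wald test
    of the exposure x subgroup product terms in the pooled model.
    """
    spec = spec or ModelSpec("M1")
    fits: dict[object, CoxFit] = {}
    for level, sub in df.groupby(subgroup_col):
        if sub[event_col].sum() == 0:
            continue
        cov_sub = [c for c in spec.covariates if c != subgroup_col]
        sub_spec = ModelSpec("M1", spec.exposure_coding, spec.ties_method,
                             spec.time_origin)
        work_cols = [exposure] + cov_sub
        try:
            _check_design(sub, work_cols)
            fits[level] = fit_cox(
                sub.assign(**{c: sub[c] for c in work_cols}),
                [exposure] + cov_sub, sub_spec, duration_col, event_col,
            )
        except ValueError:
            continue

    levels = np.sort(df[subgroup_col].unique())
    work = df.copy()
    inter_cols = []
    level_cols = []
    for lv in levels[1:]:
        ind = (work[subgroup_col] == lv).astype(float)
        lc, ic = f"_sg_{lv}", f"_int_{lv}"
        work[lc] = ind
        work[ic] = ind * work[exposure]
        level_cols.append(lc)
        inter_cols.append(ic)
    cov_main = [c for c in spec.covariates if c != subgroup_col]
    pooled_spec = ModelSpec("M1", spec.exposure_coding)
    pooled = fit_cox(
        work, [exposure] + level_cols + inter_cols + cov_main, pooled_spec,
        duration_col, event_col,
    )
    covm = pooled._cov.loc[inter_cols, inter_cols].to_numpy()
    beta = pooled.terms.loc[inter_cols, "coef"].to_numpy()
    _, _, p_inter = wald_test(beta, covm)
    return fits, float(p_inter)


def zstandardize(values, groups=None) -> np.ndarray:
    """Mean-center and scale to unit sample SD, optionally within groups."""
    v = np.asarray(values, dtype=float)
    if groups is None:
        sd = np.std(v, ddof=1)
        if sd == 0:
            raise ValueError("zero SD: z-scores undefined")
        return (v - np.mean(v)) / sd
    g = np.asarray(groups)
    out = np.empty_like(v)
    for lv in np.unique(g):
        m = g == lv
        sd = np.std(v[m], ddof=1)
        if sd == 0:
            raise ValueError(f"zero SD in group {lv!r}")
        out[m] = (v[m] - np.mean(v[m])) / sd
    return out


def logistic_sensitivity(
    df: pd.DataFrame,
    exposure_cols: list[str] | str,
    spec: ModelSpec | None = None,
    event_col: str = "event",
) -> tuple[pd.DataFrame, int]:
    """Complete-case logistic regression on the ever-dementia indicator.

    Returns an OR table (same shape as CoxFit.terms, on the odds scale)
    and the number of rows dropped for missingness.
    """
    import statsmodels.api as sm

    if isinstance(exposure_cols, str):
        exposure_cols = [exposure_cols]
    spec = spec or ModelSpec("M1")
    cols = exposure_cols + [c for c in spec.covariates if c not in exposure_cols]
    full = df[cols + [event_col]]
    data = full.dropna()
    n_dropped = len(full) - len(data)
    if data[event_col].sum() == 0:
        raise ValueError("zero cases: cannot fit logistic model")
    _check_design(data, cols)
    X = sm.add_constant(data[cols].astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(data[event_col].astype(float), X).fit(disp=0)
    params = res.params.drop("const")
    ses = res.bse.drop("const")
    table = pd.DataFrame(
        {
            "coef": params,
            "se": ses,
            "or": np.exp(params),
            "ci_lower": np.exp(params - 1.96 * ses),
            "ci_upper": np.exp(params + 1.96 * ses),
            "p": 2 * sps.norm.sf(np.abs(params / ses)),
        }
    )
    table.index.name = "term"
    return table, n_dropped
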