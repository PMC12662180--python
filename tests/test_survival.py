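"""Survival engine: Cox fits, trend test, splines, KM, subgroups, logistic."""

import numpy as np
import pandas as pd
import pytest

import cumdep as cd
from cumdep.cutpoint import logrank_statistic
from cumdep.exposures import assign_quartiles
from cumdep.survival import (
    ModelSpec,
    fit_cox,
    km_estimate,
    logistic_sensitivity,
    rcs_basis,
    rcs_fit,
    subgroup_analysis,
    trend_test,
    zstandardize,
)


def _exponential_two_groups(rng, n, ratio, censor=np.inf):
    group = rng.integers(0, 2, n)
    rate = 0.5 * ratio**group
    t = rng.exponential(1 / rate)
    event = (t <= censor).astype(int)
    return pd.DataFrame({"x": group.astype(float),
                         "time": np.minimum(t, censor), "event": event})


class TestFitCox:
    def test_exponential_rate_ratio_recovered(self, rng):
        """Two-group exponential data: HR equals the rate ratio (here 2)."""
        df = _exponential_two_groups(rng, 4000, 2.0)
        fit = fit_cox(df, "x")
        assert fit.hr("x") == pytest.approx(2.0, rel=0.08)
        lo, hi = fit.ci("x")
        assert lo < 2.0 < hi
        assert fit.n_events == 4000

    def test_constant_covariate_rejected(self, rng):
        df = _exponential_two_groups(rng, 100, 2.0)
        df["x"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_cox(df, "x")

    def test_zero_events_rejected(self, rng):
        df = _exponential_two_groups(rng, 50, 2.0)
        df["event"] = 0
        with pytest.raises(ValueError, match="zero events"):
            fit_cox(df, "x")

    def test_hr_is_exp_coef(self, rng):
        df = _exponential_two_groups(rng, 500, 2.0)
        fit = fit_cox(df, "x")
        t = fit.terms.loc["x"]
        assert t["hr"] == pytest.approx(np.exp(t["coef"]))
        assert t["ci_lower"] == pytest.approx(np.exp(t["coef"] - 1.96 * t["se"]))

    def test_breslow_flag_not_supported(self):
        with pytest.raises(NotImplementedError):
            ModelSpec("M1", ties_method="breslow")

    def test_nested_deviance_non_increasing(self, analytic_df):
        """-2 log L never increases as covariates are added M1 -> M4."""
        prev = None
        for mid in ("M1", "M2", "M3", "M4"):
            fit = fit_cox(analytic_df, "cumds", ModelSpec(mid))
            dev = -2 * fit.log_likelihood
            if prev is not None:
                assert dev <= prev + 1e-8
            prev = dev

    def test_score_test_equals_logrank(self, rng):
        """For a binary exposure the Cox score statistic at beta = 0 is the
        two-sample log-rank chi-square (checked against the cutpoint module
        implementation at 1e-6)."""
        df = _exponential_two_groups(rng, 120, 1.8, censor=3.0)
        # score statistic: U(0)^2 / I(0) accumulated over risk sets
        order = np.argsort(df["time"].to_numpy())
        t, e, x = (df["time"].to_numpy()[order], df["event"].to_numpy()[order],
                   df["x"].to_numpy()[order])
        u = 0.0
        info = 0.0
        for i in np.flatnonzero(e == 1):
            at_risk = x[t >= t[i]]
            xbar = at_risk.mean()
            u += x[i] - xbar
            info += at_risk.var()
        score_stat = u**2 / info
        lr = logrank_statistic(x.astype(int), t, e)
        # Breslow-style score test and log-rank differ only in the
        # ties/variance convention; continuous times have no ties here
        assert score_stat == pytest.approx(lr, abs=1e-6)


class TestTrendTest:
    def test_median_mapping_bookkeeping(self, analytic_df):
        """Participants are scored with their quartile's median exposure."""
        qa = assign_quartiles(analytic_df["cumds"].to_numpy())
        scored = qa.medians[qa.labels - 1]
        for q in (1, 2, 3, 4):
            assert np.allclose(scored[qa.labels == q], qa.medians[q - 1])
        work = analytic_df.copy()
        work["_trend"] = scored
        direct = fit_cox(work, "_trend")
        p = trend_test(analytic_df, qa.labels, qa.medians)
        assert p == pytest.approx(float(direct.terms.loc["_trend", "p"]), abs=1e-12)

    def test_strong_monotone_effect_detected(self, rng):
        n = 2000
        x = rng.uniform(0, 10, n)
        t = rng.exponential(1 / (0.1 * np.exp(0.25 * x)))
        df = pd.DataFrame({"x": x, "time": np.minimum(t, 15),
                           "event": (t <= 15).astype(int)})
        qa = assign_quartiles(x)
        assert trend_test(df, qa.labels, qa.medians) < 0.001

    def test_degenerate_quartiles_rejected(self, analytic_df):
        with pytest.raises(ValueError):
            trend_test(analytic_df, np.ones(len(analytic_df), int),
                       np.array([1.0, np.nan, np.nan, np.nan]))


class TestSplines:
    def test_basis_linear_beyond_boundary_knots(self):
        knots = np.array([2.0, 5.0, 8.0])
        x = np.linspace(10, 30, 50)              # beyond the upper knot
        basis = rcs_basis(x, knots)
        for j in range(basis.shape[1]):
            second_diff = np.diff(basis[:, j], 2)
            assert np.allclose(second_diff, 0, atol=1e-9)

    def test_basis_shape_and_knot_validation(self):
        assert rcs_basis(np.arange(10), [1, 4, 8]).shape == (10, 2)
        assert rcs_basis(np.arange(10), [1, 3, 5, 8]).shape == (10, 3)
        with pytest.raises(ValueError):
            rcs_basis(np.arange(10), [1, 2])
        with pytest.raises(ValueError):
            rcs_basis(np.arange(10), [3, 3, 5])

    def test_linear_slope_recovered(self, rng):
        """Under a truly linear log-hazard the spline recovers the slope."""
        n = 3000
        beta = 0.3
        x = rng.gamma(4, 1, n)
        t = rng.exponential(1 / (0.05 * np.exp(beta * (x - x.mean()))))
        df = pd.DataFrame({"x": x, "time": np.minimum(t, 20),
                           "event": (t <= 20).astype(int)})
        sp = rcs_fit(df, "x", candidate_knots=(3,))
        # fitted curve slope between reference and reference+1
        grid = sp.curve
        slope = np.polyfit(grid["exposure"], grid["loghr"], 1)[0]
        assert slope == pytest.approx(beta, abs=0.05)
        assert sp.p_overall < 0.001

    def test_bic_selection_recorded(self, analytic_df):
        sp = rcs_fit(analytic_df, "cumads")
        assert set(sp.bic_by_knots) == {3, 4, 5}
        assert sp.n_knots == min(sp.bic_by_knots, key=sp.bic_by_knots.get)
        assert np.isfinite(sp.p_nonlinear)
        assert sp.reference_value == pytest.approx(
            float(np.median(analytic_df["cumads"]))
        )
        # curve passes through zero at the reference value
        i = np.argmin(np.abs(sp.curve["exposure"] - sp.reference_value))
        assert abs(sp.curve["loghr"].iloc[i]) < 0.05

    def test_too_few_distinct_values(self, rng):
        df = pd.DataFrame({"x": np.tile([1.0, 2.0], 25),
                           "time": rng.exponential(1, 50),
                           "event": np.ones(50, int)})
        with pytest.raises(ValueError):
            rcs_fit(df, "x")


class TestKaplanMeier:
    def test_hand_product_limit(self):
        df = pd.DataFrame({"g": [0, 0, 0], "time": [1.0, 2.0, 3.0],
                           "event": [1, 0, 1]})
        est = km_estimate(df, "g")
        curve = est.curves[0].set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(2 / 3)
        assert curve.loc[3.0] == pytest.approx(0.0)

    def test_no_events_survival_one(self):
        df = pd.DataFrame({"g": [0, 0, 1, 1], "time": [1, 2, 3, 4.0],
                           "event": [0, 0, 0, 0]})
        est = km_estimate(df, "g")
        for curve in est.curves.values():
            assert (curve["survival"] == 1.0).all()
        assert np.isnan(est.logrank_p)

    def test_no_censoring_matches_empirical_survival(self, rng):
        t = rng.exponential(2, 200)
        df = pd.DataFrame({"g": 0, "time": t, "event": 1})
        est = km_estimate(df, "g")
        curve = est.curves[0]
        emp = 1 - np.searchsorted(np.sort(t), curve["time"], side="right") / 200
        np.testing.assert_allclose(curve["survival"], emp, atol=1e-10)

    def test_ordered_hazards_give_ordered_curves(self, rng):
        n = 2000
        q = rng.integers(1, 5, n)
        t = rng.exponential(1 / (0.05 * 2.0 ** (q - 1)))
        df = pd.DataFrame({"g": q, "time": np.minimum(t, 10),
                           "event": (t <= 10).astype(int)})
        est = km_estimate(df, "g")
        s5 = [np.interp(5.0, est.curves[k]["time"], est.curves[k]["survival"])
              for k in (1, 2, 3, 4)]
        assert np.all(np.diff(s5) < 0)
        assert est.logrank_p < 0.001


class TestSubgroupAndSensitivity:
    def test_output_shape_two_level_subgroup(self, analytic_df):
        fits, p_inter = subgroup_analysis(analytic_df, "cumds", "female")
        assert set(fits) == {0, 1}
        assert 0 <= p_inter <= 1
        for fit in fits.values():
            assert "cumds" in fit.terms.index

    def test_zstandardize_example(self):
        np.testing.assert_allclose(zstandardize([2, 4, 6]), [-1, 0, 1])

    def test_zstandardize_per_group(self, rng):
        v = rng.normal(5, 3, 200)
        g = rng.integers(0, 2, 200)
        z = zstandardize(v, g)
        for lv in (0, 1):
            assert np.mean(z[g == lv]) == pytest.approx(0, abs=1e-12)
            assert np.std(z[g == lv], ddof=1) == pytest.approx(1, abs=1e-12)
        with pytest.raises(ValueError):
            zstandardize(np.ones(5))

    def test_per_sd_hr_is_power_of_per_unit_hr(self, analytic_df):
        """HR per 1 SD equals the per-unit HR raised to the SD."""
        sd = np.std(analytic_df["cumds"], ddof=1)
        per_unit = fit_cox(analytic_df, "cumds")
        work = analytic_df.copy()
        work["z"] = zstandardize(work["cumds"].to_numpy())
        per_sd = fit_cox(work, "z")
        assert per_sd.hr("z") == pytest.approx(per_unit.hr("cumds") ** sd, rel=1e-6)

    def test_logistic_complete_case_bookkeeping(self, analytic_df):
        work = analytic_df.copy()
        work.loc[work.index[:13], "cumds"] = np.nan
        table, dropped = logistic_sensitivity(work, "cumds")
        assert dropped == 13
        assert {"or", "ci_lower", "ci_upper", "p"} <= set(table.columns)

    def test_logistic_rare_outcome_close_to_hr(self, rng):
        """With <=5% incidence the OR approximates the HR."""
        n = 6000
        x = rng.normal(0, 2, n)
        rate = 0.005 * np.exp(np.log(1.3) * x)
        t = rng.exponential(1 / rate)
        df = pd.DataFrame({"x": x, "time": np.minimum(t, 8),
                           "event": (t <= 8).astype(int)})
        assert df["event"].mean() < 0.07
        cox = fit_cox(df, "x")
        logi, _ = logistic_sensitivity(df, "x")
        assert float(logi.loc["x", "or"]) == pytest.approx(cox.hr("x"), rel=0.10)
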