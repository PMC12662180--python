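"""Algorithmic dementia ascertainment: norms, rules, absorbing state, lag."""

import numpy as np
import pandas as pd
import pytest

import cumdep as cd
from cumdep.classify import (
    CohortNorms,
    classify_dementia,
    cognitive_impairment,
    compute_norms,
    functional_impairment,
    lagged_exclusion,
)


def _panel(rows):
    return pd.DataFrame(rows)


class TestNorms:
    def test_stratum_mean_and_sd(self):
        panel = _panel([
            {"id": i, "wave": 1, "education": "hs",
             "memory": m, "orientation": 4, "executive": e}
            for i, (m, e) in enumerate([(10, 3), (12, 4), (14, 5)])
        ])
        norms = compute_norms(panel, domains=("memory",))
        mean, sd = norms.get("hs", "memory")
        assert mean == pytest.approx(12.0)
        assert sd == pytest.approx(2.0)

    def test_single_participant_stratum_raises(self):
        panel = _panel([
            {"id": 0, "wave": 1, "education": "hs", "memory": 10},
            {"id": 1, "wave": 1, "education": "college", "memory": 12},
            {"id": 2, "wave": 1, "education": "college", "memory": 14},
        ])
        with pytest.raises(ValueError):
            compute_norms(panel, domains=("memory",))

    def test_no_pooling_across_strata(self):
        panel = _panel(
            [{"id": i, "wave": 1, "education": "hs", "memory": m}
             for i, m in enumerate([8, 10, 12])]
            + [{"id": 10 + i, "wave": 1, "education": "college", "memory": m}
               for i, m in enumerate([14, 16, 18])]
        )
        norms = compute_norms(panel, domains=("memory",))
        assert norms.get("hs", "memory")[0] == pytest.approx(10.0)
        assert norms.get("college", "memory")[0] == pytest.approx(16.0)


class TestImpairment:
    norms = CohortNorms({("hs", "memory"): (12.0, 2.0),
                         ("hs", "orientation"): (3.5, 0.5)},
                        domains=("memory", "orientation"))

    def test_boundary_inclusive(self):
        assert cognitive_impairment({"memory": 9.0}, self.norms, "hs")
        assert not cognitive_impairment({"memory": 9.1}, self.norms, "hs")

    def test_any_domain_rule(self):
        scores = {"memory": 12.0, "orientation": 2.5}   # orientation 2 SD below
        assert cognitive_impairment(scores, self.norms, "hs")

    def test_functional(self):
        assert not functional_impairment(0)
        assert functional_impairment(1)
        assert functional_impairment(5)
        with pytest.raises(ValueError):
            functional_impairment(-1)


def _summary_panel(composites, self_report=False):
    return _panel([
        {"id": 0, "wave": w + 1, "education": "hs", "adl": 0,
         "self_report": self_report, "cog_summary": comp}
        for w, comp in enumerate(composites)
    ])


class TestClassification:
    def test_summary_score_cut_boundary(self):
        """Composite at the cut classifies as dementia; one above does not."""
        pos = classify_dementia(_summary_panel([20, 6, 5]), rule="summary_score")
        assert pos["status"].tolist() == [False, True, True]
        assert pos["first_positive_wave"].iloc[0] == 2
        neg = classify_dementia(_summary_panel([20, 7, 8]), rule="summary_score")
        assert not neg["status"].any()

    def test_concurrence_requires_both(self):
        norms = CohortNorms({("hs", "memory"): (12.0, 2.0)}, domains=("memory",))
        panel = _panel([
            {"id": 0, "wave": 1, "education": "hs", "memory": 8.0,
             "adl": 0, "self_report": False},
        ])
        res = classify_dementia(panel, norms)
        assert not res["status"].any()       # impaired cognition, no ADL
        panel["adl"] = 1
        res = classify_dementia(panel, norms)
        assert res["status"].all()

    def test_self_report_under_either_basis(self):
        norms = CohortNorms({("hs", "memory"): (12.0, 2.0)}, domains=("memory",))
        panel = _panel([
            {"id": 0, "wave": 1, "education": "hs", "memory": 12.0,
             "adl": 0, "self_report": True},
        ])
        assert classify_dementia(panel, norms, basis="either")["status"].all()
        assert not classify_dementia(panel, norms, basis="algorithmic")["status"].any()

    def test_adl_beyond_first_is_irrelevant(self):
        norms = CohortNorms({("hs", "memory"): (12.0, 2.0)}, domains=("memory",))
        rows = [{"id": 0, "wave": 1, "education": "hs", "memory": 8.0,
                 "adl": 1, "self_report": False}]
        one = classify_dementia(_panel(rows), norms)
        rows[0]["adl"] = 7
        many = classify_dementia(_panel(rows), norms)
        pd.testing.assert_frame_equal(one, many)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            classify_dementia(_summary_panel([5]), rule="majority_vote")


class TestOnSyntheticCohort:
    def test_absorbing_state(self, small_cohort):
        norms = compute_norms(small_cohort.panel)
        res = classify_dementia(small_cohort.panel, norms)
        for _, g in res.groupby("id"):
            s = g.sort_values("wave")["status"].astype(int).to_numpy()
            assert np.all(np.diff(s) >= 0)

    def test_perfect_recovery_without_noise(self, small_cohort):
        """Zero-noise planting gives sensitivity and specificity 1."""
        norms = compute_norms(small_cohort.panel)
        res = classify_dementia(small_cohort.panel, norms)
        flat = res.drop_duplicates("id").set_index("id")
        truth = small_cohort.participants.set_index("id")
        detected = flat["first_positive_wave"].notna()
        assert (detected == (truth["event"] == 1)).all()
        ev = truth["event"] == 1
        assert (flat.loc[ev.index[ev], "first_positive_wave"]
                == truth.loc[ev, "event_wave"]).all()


class TestLaggedExclusion:
    def _classified(self, first_waves):
        rows = []
        for i, fw in enumerate(first_waves):
            for w in (1, 2, 3):
                rows.append({"id": i, "wave": w,
                             "status": fw is not None and w >= fw,
                             "first_positive_wave": fw})
        return pd.DataFrame(rows)

    def test_counts(self):
        df = self._classified([None] * 93 + [2] * 7)
        out = lagged_exclusion(df)
        assert out["id"].nunique() == 93
        assert not (out["first_positive_wave"] == 2).any()

    def test_identity_when_no_wave2_cases(self):
        df = self._classified([None, 3, None])
        pd.testing.assert_frame_equal(lagged_exclusion(df), df)

    def test_all_events_removed_breaks_downstream_fit(self):
        """If every case was incident at wave 2, the lagged Cox fit has
        zero events and the survival stage raises."""
        df = self._classified([2, 2, None, None])
        out = lagged_exclusion(df)
        surv = pd.DataFrame({
            "id": out["id"].unique(),
            "time": [5.0, 6.0],
            "event": [0, 0],
            "x": [1.0, 2.0],
        })
        with pytest.raises(ValueError, match="zero events"):
            cd.fit_cox(surv, "x")
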