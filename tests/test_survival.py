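"""Kaplan-Meier, log-rank, Cox (incl. time-varying), AUC(t) and calibration."""

import numpy as np
import pandas as pd
import pytest

from hlamm.single_molecule import mann_whitney_auc
from hlamm.survival import (
    calibration_curve,
    cumulative_event_curve,
    expand_time_varying,
    fit_ph_model,
    logrank,
    time_dependent_auc,
)
from hlamm.synthetic import generate_cox_data, generate_group_survival_data


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        # 5 subjects: events at 1, 3, 4; censored at 2 and 5
        times = [1, 2, 3, 4, 5]
        events = [True, False, True, True, False]
        curve = cumulative_event_curve(times, events)[0]
        by_time = dict(zip(curve["time"], curve["cum_event"]))
        assert by_time[1.0] == pytest.approx(1 - 4 / 5)
        assert by_time[3.0] == pytest.approx(1 - 4 / 5 * 2 / 3)
        assert by_time[4.0] == pytest.approx(1 - 4 / 5 * 2 / 3 * 1 / 2)

    def test_no_censoring_equals_ecdf(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1.0, size=50)
        curve = cumulative_event_curve(t, np.ones(50, dtype=bool))[0]
        ecdf = np.searchsorted(np.sort(t), curve["time"], side="right") / 50
        assert np.allclose(curve["cum_event"], ecdf)

    def test_all_censored_flat_zero(self):
        curve = cumulative_event_curve([1, 2, 3], [False] * 3)[0]
        assert (curve["cum_event"] == 0).all()

    def test_monotone_and_bands_contain_estimate(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(2.0, size=100)
        e = rng.random(100) < 0.7
        curve = cumulative_event_curve(t, e)[0]
        assert (np.diff(curve["cum_event"]) >= -1e-12).all()
        assert (curve["ci_lo"] <= curve["cum_event"] + 1e-12).all()
        assert (curve["ci_hi"] >= curve["cum_event"] - 1e-12).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cumulative_event_curve([], [], None)


class TestLogrank:
    def test_identical_groups_zero_statistic(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 0, 1, 1, 0, 1]
        g = [0, 0, 0, 1, 1, 1]
        stat, p = logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_subject_hand_calculation(self):
        # group A: event at 1; group B: event at 2, censored at 3.
        # O-E for A = 2/3, Var = 2/9 -> chi2 = 2.0
        stat, p = logrank([1, 2, 3], [1, 1, 0], ["A", "B", "B"])
        assert stat == pytest.approx(2.0, abs=1e-9)
        assert p == pytest.approx(0.15729, abs=1e-4)

    def test_invariant_under_time_rescaling(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1.0, size=60)
        e = rng.random(60) < 0.8
        g = rng.integers(0, 2, size=60)
        s1, _ = logrank(t, e, g)
        s2, _ = logrank(t * 7.3, e, g)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([1, 2], [1, 1], [0, 0])


class TestCox:
    def test_null_covariate_hr_near_one(self):
        df = generate_group_survival_data(800, hazard_ratio=1.0, seed=3)
        fit = fit_ph_model(df, "time", "event", ["high"])
        row = fit.summary.loc["high"]
        assert row["hr_lo"] < 1.0 < row["hr_hi"]
        assert abs(row["coef"]) < 0.25

    def test_known_hazard_ratio_recovered(self):
        df = generate_group_survival_data(1500, hazard_ratio=2.0, seed=4)
        fit = fit_ph_model(df, "time", "event", ["high"])
        assert fit.summary.loc["high", "coef"] == pytest.approx(np.log(2.0), abs=0.15)
        assert np.exp(fit.summary.loc["high", "coef"]) == pytest.approx(
            fit.summary.loc["high", "hr"], rel=1e-10
        )

    def test_duplicated_data_same_coef_shrunk_ci(self):
        df = generate_group_survival_data(300, hazard_ratio=2.0, seed=5)
        fit1 = fit_ph_model(df, "time", "event", ["high"])
        df4 = pd.concat([df] * 4, ignore_index=True)
        fit4 = fit_ph_model(df4, "time", "event", ["high"])
        # duplication creates 4-way event-time ties, so the Efron correction
        # perturbs the coefficient slightly; information still scales by 4
        assert fit4.summary.loc["high", "coef"] == pytest.approx(
            fit1.summary.loc["high", "coef"], abs=5e-3
        )
        w1 = np.log(fit1.summary.loc["high", "hr_hi"] / fit1.summary.loc["high", "hr_lo"])
        w4 = np.log(fit4.summary.loc["high", "hr_hi"] / fit4.summary.loc["high", "hr_lo"])
        assert w4 == pytest.approx(w1 / 2, rel=0.02)  # CI width ~ 1/sqrt(4)


class TestTimeVarying:
    def _manual_long(self):
        # 4 subjects, DSA switch at known times; hand-expanded intervals
        return pd.DataFrame(
            [
                ("A", 0.0, 2.0, 0, 0), ("A", 2.0, 5.0, 1, 1),
                ("B", 0.0, 3.0, 0, 0),
                ("C", 0.0, 1.0, 0, 0), ("C", 1.0, 4.0, 1, 1),
                ("D", 0.0, 2.0, 0, 1),
            ],
            columns=["pair_id", "start", "stop", "dsa", "event"],
        )

    def _wide(self):
        return pd.DataFrame(
            {
                "pair_id": ["A", "B", "C", "D"],
                "time": [5.0, 3.0, 4.0, 2.0],
                "event": [True, False, True, True],
                "dsa_time": [2.0, np.nan, 1.0, 3.0],  # D switches after its event
            }
        )

    def test_expansion_matches_manual_table(self):
        long = expand_time_varying(self._wide(), "time", "event", {"dsa": "dsa_time"})
        got = long[["pair_id", "start", "stop", "dsa", "event"]].copy()
        got["event"] = got["event"].astype(int)
        got = got.sort_values(["pair_id", "start"]).reset_index(drop=True)
        want = self._manual_long().sort_values(["pair_id", "start"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(got.astype({"dsa": int}), want.astype({"dsa": int}))

    def test_identical_partial_likelihood(self):
        from lifelines import CoxTimeVaryingFitter

        fit = fit_ph_model(
            self._wide(), "time", "event", [], time_varying={"dsa": "dsa_time"}
        )
        manual = CoxTimeVaryingFitter()
        manual.fit(self._manual_long(), id_col="pair_id", start_col="start",
                   stop_col="stop", event_col="event")
        assert fit.summary.loc["dsa", "coef"] == pytest.approx(
            manual.summary.loc["dsa", "coef"], abs=1e-10
        )
        assert fit.fitter.log_likelihood_ == pytest.approx(manual.log_likelihood_, abs=1e-10)


class TestTimeDependentAuc:
    def test_zero_censoring_reduces_to_mann_whitney(self):
        rng = np.random.default_rng(6)
        n = 150
        scores = rng.normal(size=n)
        times = rng.exponential(np.exp(-scores), size=n)
        events = np.ones(n, dtype=bool)
        for t in (0.3, 0.8, 1.5):
            res = time_dependent_auc(scores, times, events, [t])
            labels = times <= t
            assert res.auc_t[0] == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-10
            )

    def test_perfect_ranking_gives_auc_one(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        scores = -times  # higher risk = earlier event
        res = time_dependent_auc(scores, times, np.ones(5, bool), [1.5, 2.5, 3.5])
        assert np.allclose(res.auc_t, 1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(7)
        n = 2000
        times = rng.exponential(1.0, size=n)
        scores = rng.normal(size=n)
        res = time_dependent_auc(scores, times, np.ones(n, bool), [1.0])
        assert res.auc_t[0] == pytest.approx(0.5, abs=0.05)

    def test_agrees_with_scikit_survival(self):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(8)
        n = 300
        scores = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.8 * scores))
        c = rng.exponential(2.0, size=n)
        times = np.minimum(t, c)
        events = t <= c
        y = Surv.from_arrays(events, times)
        eval_times = [0.5, 1.0, 1.5]
        ours = time_dependent_auc(scores, times, events, eval_times)
        theirs, _ = cumulative_dynamic_auc(y, y, scores, eval_times)
        assert np.allclose(ours.auc_t, theirs, atol=0.02)

    def test_eval_time_beyond_followup_flagged(self):
        res = time_dependent_auc([1, 2], [1.0, 2.0], [True, True], [10.0])
        assert np.isnan(res.auc_t[0])


class TestCalibration:
    def test_constant_predictions_single_marginal_group(self):
        rng = np.random.default_rng(9)
        n = 120
        df = pd.DataFrame(
            {
                "time": rng.exponential(4.0, size=n),
                "event": True,
                "x0": 1.0,  # no variation: model predicts a constant risk
            }
        )
        df["event"] = df["time"] < 8.0
        df.loc[~df["event"], "time"] = 8.0
        curve = calibration_curve(
            df, "time", "event", ["x0"], horizon=2.0, n_boot=5, seed=0
        )
        assert len(curve) == 1
        marginal = cumulative_event_curve(df["time"], df["event"])[0]
        km_at_2 = marginal[marginal["time"] <= 2.0]["cum_event"].iloc[-1]
        assert curve["observed"].iloc[0] == pytest.approx(km_at_2, abs=1e-9)

    def test_horizon_beyond_followup_rejected(self):
        df = generate_cox_data(50, seed=10)
        with pytest.raises(ValueError, match="horizon"):
            calibration_curve(df, "time", "event", ["x0", "x1"], horizon=1e6, n_boot=1)
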