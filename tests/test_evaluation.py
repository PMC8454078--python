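import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from mlas.cox import WeightedCoxResults
from mlas.errors import EstimationError, ValidationError
from mlas.evaluation import (
    bland_altman,
    bootstrap_compare,
    calibration_table,
    kaplan_meier,
    km_at,
    td_roc_nne,
)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.integers(1, 50, 200).astype(float)
        km = kaplan_meier(t, np.ones(200, dtype=int))
        for _, row in km.iterrows():
            assert row["survival"] == pytest.approx((t > row["time"]).mean())

    def test_hand_product_limit(self):
        # times 1+, 2, 3+, 4: S(2) = 2/3, S(4) = 0
        km = kaplan_meier([1, 2, 3, 4], [0, 1, 0, 1]).set_index("time")
        assert km.loc[2, "survival"] == pytest.approx(2 / 3)
        assert km.loc[4, "survival"] == pytest.approx(0.0)

    def test_doubling_observations_leaves_estimate_unchanged(self):
        t = np.array([2.0, 3.0, 5.0, 7.0, 11.0])
        e = np.array([1, 0, 1, 1, 0])
        a = kaplan_meier(t, e)
        b = kaplan_meier(np.repeat(t, 2), np.repeat(e, 2))
        np.testing.assert_allclose(
            a["survival"].to_numpy(), b["survival"].to_numpy()
        )

    def test_all_censored_warns_and_is_one(self):
        with pytest.warns(UserWarning, match="censored"):
            km = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert (km["survival"] == 1.0).all()


class TestTdRoc:
    def test_perfect_marker(self):
        t = np.array([100.0] * 50 + [400.0] * 50)
        m = np.concatenate([np.linspace(1, 2, 50), np.linspace(-2, -1, 50)])
        roc = td_roc_nne(m, t, np.ones(100, dtype=int), t_star=365)
        assert roc.auc == pytest.approx(1.0)

    def test_constant_marker_is_uninformative(self):
        rng = np.random.default_rng(1)
        t = rng.integers(1, 500, 80).astype(float)
        roc = td_roc_nne(np.zeros(80), t, np.ones(80, dtype=int), t_star=250)
        assert roc.auc == pytest.approx(0.5)

    def test_no_censoring_equals_mann_whitney(self):
        rng = np.random.default_rng(2)
        n = 200
        m = rng.normal(size=n)  # ties-free continuous marker
        t = np.ceil(rng.exponential(300 * np.exp(-0.8 * m)))
        roc = td_roc_nne(m, t, np.ones(n, dtype=int), t_star=365)
        assert not roc.smoothed
        want = roc_auc_score((t <= 365).astype(int), m)
        assert roc.auc == pytest.approx(want, abs=1e-12)

    def test_censoring_uses_smoothing_and_stays_valid(self):
        rng = np.random.default_rng(3)
        n = 300
        m = rng.normal(size=n)
        t = np.ceil(rng.exponential(300 * np.exp(-0.8 * m)))
        c = np.ceil(rng.exponential(400, n))
        obs = np.minimum(t, c)
        ev = (t <= c).astype(int)
        roc = td_roc_nne(m, obs, ev, t_star=365)
        assert roc.smoothed
        assert 0.5 < roc.auc <= 1.0
        # ROC endpoints and monotonicity over the threshold grid
        assert roc.sensitivity[0] == 1.0 and roc.specificity[0] == 0.0
        assert (np.diff(roc.sensitivity) <= 1e-12).all()
        assert (np.diff(1.0 - roc.specificity) <= 1e-12).all()

    def test_smoothed_auc_close_to_uncensored_truth(self):
        rng = np.random.default_rng(4)
        n = 600
        m = rng.normal(size=n)
        t = np.ceil(rng.exponential(300 * np.exp(-0.8 * m)))
        full = td_roc_nne(m, t, np.ones(n, dtype=int), t_star=365).auc
        c = np.ceil(rng.exponential(600, n))
        obs, ev = np.minimum(t, c), (t <= c).astype(int)
        cens = td_roc_nne(m, obs, ev, t_star=365).auc
        assert cens == pytest.approx(full, abs=0.05)

    def test_degenerate_roc_raises(self):
        with pytest.raises(EstimationError):
            td_roc_nne([1.0, 2.0], [500.0, 600.0], [1, 1], t_star=365)

    def test_span_validation(self):
        with pytest.raises(ValidationError, match="span"):
            td_roc_nne([1.0, 2.0], [10.0, 600.0], [1, 1], t_star=365, span=1.5)


class TestBootstrap:
    @staticmethod
    def _mean(d):
        return d["y"].mean()

    def test_identical_pipelines_degenerate_comparison(self):
        d = pd.DataFrame({"patient_id": range(50),
                          "y": np.random.default_rng(0).normal(size=50)})
        cmp = bootstrap_compare(self._mean, self._mean, d, reps=50, seed=1)
        assert cmp.difference == 0.0
        assert cmp.p_value == 1.0
        assert cmp.ci_difference == (0.0, 0.0)

    def test_fixed_seed_bit_reproducible(self):
        rng = np.random.default_rng(5)
        d = pd.DataFrame({"patient_id": range(40), "y": rng.normal(size=40)})
        other = lambda x: x["y"].median()
        a = bootstrap_compare(self._mean, other, d, reps=100, seed=11)
        b = bootstrap_compare(self._mean, other, d, reps=100, seed=11)
        assert a.ci_a == b.ci_a and a.ci_difference == b.ci_difference
        assert a.p_value == b.p_value

    def test_patient_rows_move_together(self):
        # two rows per patient with equal values: the per-patient mean of the
        # replicate data must keep them paired
        d = pd.DataFrame(
            {"patient_id": np.repeat(range(30), 2),
             "y": np.repeat(np.arange(30.0), 2)}
        )
        def paired_check(data):
            g = data.groupby("patient_id")["y"].agg(["min", "max", "size"])
            assert (g["min"] == g["max"]).all() and (g["size"] == 2).all()
            return data["y"].mean()
        bootstrap_compare(paired_check, paired_check, d, reps=5, seed=3)


class TestCalibration:
    def make_fit(self, h=2e-3, beta=0.7):
        H = np.concatenate([[0.0], h * np.arange(1, 366)])
        return WeightedCoxResults(
            covariates=["x"], params=pd.Series({"x": beta}),
            baseline_cumulative_hazard=H,
            log_likelihood=0.0, n_iter=1, converged=True, n_obs=1, n_events=1,
        )

    def test_tertile_partition_of_nine(self):
        fit = self.make_fit()
        rng = np.random.default_rng(6)
        d = pd.DataFrame({"x": rng.normal(size=9)})
        d["time"] = 400.0
        d["event"] = 1
        d.loc[0, "time"] = 100.0
        tab = calibration_table(fit, d)
        counts = tab.groupby("group")["n"].first()
        assert sorted(counts) == [3, 3, 3]

    def test_zero_event_group_warns(self):
        fit = self.make_fit()
        d = pd.DataFrame({"x": np.arange(9.0), "time": 400.0, "event": 0})
        with pytest.warns(UserWarning, match="zero events"):
            calibration_table(fit, d)

    def test_constant_covariate_cohort_single_group(self):
        fit = self.make_fit()
        d = pd.DataFrame({"x": np.zeros(30), "time": 200.0, "event": 1})
        tab = calibration_table(fit, d)
        # boundary ties all go to the lower-risk group
        assert set(tab["group"]) == {"low"}

    def test_self_consistency_on_model_generated_data(self):
        # data drawn from the fitted law itself must reproduce the predicted
        # curves within Monte-Carlo error
        fit = self.make_fit(h=2e-3, beta=0.7)
        rng = np.random.default_rng(7)
        n = 10_000
        x = rng.normal(size=n)
        lam = 2e-3 * np.exp(0.7 * x)
        t = np.ceil(rng.exponential(1.0 / lam))
        c = np.ceil(rng.uniform(50, 800, n))
        d = pd.DataFrame(
            {"x": x, "time": np.minimum(t, c), "event": (t <= c).astype(int)}
        )
        tab = calibration_table(fit, d)
        assert (tab["predicted"] - tab["observed"]).abs().max() < 0.03


class TestBlandAltman:
    def test_identical_inputs(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.mean_difference == 0.0 and ba.sd_difference == 0.0
        assert ba.lower_limit == ba.upper_limit == 0.0

    def test_hand_example(self):
        ba = bland_altman([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        np.testing.assert_allclose(ba.differences, [-1.0, 0.0, 1.0])
        assert ba.mean_difference == 0.0
        assert ba.sd_difference == pytest.approx(1.0)  # n-1 denominator
        assert (ba.lower_limit, ba.upper_limit) == (-2.0, 2.0)

    def test_limits_symmetric_about_mean(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=50), rng.normal(size=50)
        ba = bland_altman(a, b)
        mid = 0.5 * (ba.lower_limit + ba.upper_limit)
        assert mid == pytest.approx(ba.mean_difference)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0], [1.0, 2.0])
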