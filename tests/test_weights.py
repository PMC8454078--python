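import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from mlas.errors import DegenerateModelError
from mlas.weights import (
    DiscreteHazard,
    fit_discrete_hazard,
    post_transplant_weights,
    pre_transplant_weights,
    weight_diagnostics,
)


def make_rows(n_patients, n_days, p_tx=0.0, p_cens=0.0, rng=None, x_effect=0.0):
    """Synthetic counting rows with constant daily exit probabilities."""
    rng = rng or np.random.default_rng(0)
    recs = []
    for i in range(n_patients):
        x = rng.normal()
        for day in range(1, n_days + 1):
            p = expit(logit(max(p_tx, 1e-12)) + x_effect * x) if p_tx else 0.0
            tx = rng.random() < p
            cens = (not tx) and (rng.random() < p_cens)
            recs.append(
                {
                    "patient_id": i, "start": day - 1, "stop": day, "x": x,
                    "event_transplant": int(tx), "event_censor": int(cens),
                    "event_death": 0,
                }
            )
            if tx or cens:
                break
    return pd.DataFrame(recs)


def manual_model(target, intercept_prob):
    """A hazard model with a hand-set constant daily probability."""
    m = DiscreteHazard(target, covariates=(), time_knots=0)
    m.params_ = np.array([logit(intercept_prob) if intercept_prob > 0 else -60.0])
    m.converged = True
    return m


class TestDiscreteHazard:
    def test_intercept_only_recovers_event_rate(self):
        rows = make_rows(200, 30, p_tx=0.05)
        m = fit_discrete_hazard(rows, "transplant", time_knots=0)
        rate = rows["event_transplant"].mean()
        assert m.predict_hazard(rows.iloc[:1])[0] == pytest.approx(rate, rel=1e-6)

    def test_null_covariate_effect_is_near_zero(self):
        # x enters the design but has no effect in the generating law
        rows = make_rows(400, 40, p_tx=0.03, rng=np.random.default_rng(1))
        m = fit_discrete_hazard(rows, "transplant", ["x"], time_knots=0)
        assert abs(m.params_[-1]) < 0.1  # ~3 SE at this event count

    def test_matches_handwritten_newton_raphson(self):
        rows = make_rows(5, 4, p_tx=0.3, x_effect=0.8,
                         rng=np.random.default_rng(4))
        rows = rows.iloc[:20]
        m = fit_discrete_hazard(rows, "transplant", ["x"], time_knots=0)
        X = m.design(rows)
        y = rows["event_transplant"].to_numpy(dtype=float)
        b = np.zeros(X.shape[1])
        for _ in range(200):
            p = expit(X @ b)
            g = X.T @ (y - p)
            H = (X * (p * (1 - p))[:, None]).T @ X
            b = b + np.linalg.solve(H, g)
            if np.max(np.abs(g)) < 1e-12:
                break
        np.testing.assert_allclose(m.params_, b, atol=1e-8)

    def test_zero_events_is_degenerate(self):
        rows = make_rows(10, 5)
        with pytest.raises(DegenerateModelError, match="transplant"):
            fit_discrete_hazard(rows, "transplant")


class TestPreTransplantWeights:
    def test_identical_numerator_denominator_gives_unit_weights(self):
        rows = make_rows(50, 20, p_tx=0.05, p_cens=0.02,
                         rng=np.random.default_rng(2))
        den_t = fit_discrete_hazard(rows, "transplant", time_knots=0)
        den_c = fit_discrete_hazard(rows, "censor", time_knots=0)
        w = pre_transplant_weights(rows, den_t, den_c, den_t, den_c,
                                   truncation=None)
        np.testing.assert_allclose(w["weight"], 1.0, atol=1e-12)

    def test_zero_hazards_give_unit_weights(self):
        rows = make_rows(10, 5)
        z_t, z_c = manual_model("transplant", 0.0), manual_model("censor", 0.0)
        w = pre_transplant_weights(rows, z_t, z_c, z_t, z_c, truncation=None)
        np.testing.assert_allclose(w["weight"], 1.0, atol=1e-9)

    def test_two_day_hand_example(self):
        # denominator daily transplant prob 0.2, numerator 0.1, no censoring:
        # w(1) = 0.9/0.8 = 1.125, w(2) = 1.125^2
        rows = make_rows(1, 2)
        w = pre_transplant_weights(
            rows,
            manual_model("transplant", 0.2),
            manual_model("censor", 0.0),
            manual_model("transplant", 0.1),
            manual_model("censor", 0.0),
            truncation=None,
        )
        np.testing.assert_allclose(w["weight"], [1.125, 1.125**2], atol=1e-9)

    def test_truncation_never_increases_max(self):
        rows = make_rows(100, 30, p_tx=0.08, p_cens=0.02, x_effect=1.0,
                         rng=np.random.default_rng(3))
        den_t = fit_discrete_hazard(rows, "transplant", ["x"], time_knots=0)
        den_c = fit_discrete_hazard(rows, "censor", time_knots=0)
        num_t = fit_discrete_hazard(rows, "transplant", time_knots=0)
        num_c = fit_discrete_hazard(rows, "censor", time_knots=0)
        free = pre_transplant_weights(rows, den_t, den_c, num_t, num_c,
                                      truncation=None)
        trunc = pre_transplant_weights(rows, den_t, den_c, num_t, num_c,
                                       truncation=(1.0, 99.0))
        assert trunc["weight"].max() <= free["weight"].max()
        lo, hi = trunc.attrs["truncation_bounds"]
        assert trunc["weight"].max() <= hi + 1e-12


class TestPostTransplantWeights:
    def test_identical_models_give_unit_weights(self):
        rows = make_rows(80, 15, p_tx=0.05, rng=np.random.default_rng(5))
        den_t = fit_discrete_hazard(rows, "transplant", time_knots=0)
        den_c = manual_model("censor", 0.0)
        w = post_transplant_weights(rows, den_t, den_c, den_t, den_c,
                                    truncation=None)
        assert len(w) == rows["event_transplant"].sum()
        np.testing.assert_allclose(w["weight"], 1.0, atol=1e-12)

    def test_day_one_transplant_hand_example(self):
        # transplant on day 1: weight = num/den = 0.25/0.5
        rows = make_rows(1, 1)
        rows.loc[0, "event_transplant"] = 1
        w = post_transplant_weights(
            rows,
            manual_model("transplant", 0.5),
            manual_model("censor", 0.0),
            manual_model("transplant", 0.25),
            manual_model("censor", 0.0),
            truncation=None,
        )
        assert w["weight"].iloc[0] == pytest.approx(0.5, abs=1e-12)
        assert w["tx_day"].iloc[0] == 1

    def test_excluding_transplant_day_factor(self):
        rows = make_rows(1, 1)
        rows.loc[0, "event_transplant"] = 1
        w = post_transplant_weights(
            rows,
            manual_model("transplant", 0.5),
            manual_model("censor", 0.0),
            manual_model("transplant", 0.25),
            manual_model("censor", 0.0),
            truncation=None,
            include_tx_day=False,
        )
        # only survival-to-transplant remains; the day-1 cumulative is empty
        assert w["weight"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_weighted_transplant_count_under_random_selection(self):
        # with selection independent of covariates, the stabilized weights
        # preserve the transplanted headcount
        rows = make_rows(2000, 40, p_tx=0.03, p_cens=0.01,
                         rng=np.random.default_rng(6))
        den_t = fit_discrete_hazard(rows, "transplant", ["x"])
        den_c = fit_discrete_hazard(rows, "censor")
        num_t = fit_discrete_hazard(rows, "transplant")
        num_c = fit_discrete_hazard(rows, "censor")
        w = post_transplant_weights(rows, den_t, den_c, num_t, num_c,
                                    truncation=None)
        n_tx = rows["event_transplant"].sum()
        assert w["weight"].sum() == pytest.approx(n_tx, rel=0.05)


class TestDiagnostics:
    def test_unit_weights_summary(self):
        w = pd.DataFrame({"weight": np.ones(100)})
        s = weight_diagnostics(w)
        assert s["mean"].iloc[0] == 1.0 and s["sd"].iloc[0] == 0.0
        assert not s["flagged"].iloc[0]

    def test_percentiles_match_sort_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.lognormal(size=501)
        s = weight_diagnostics(pd.DataFrame({"weight": vals}))
        for q, col in ((1, "p1"), (50, "p50"), (99, "p99")):
            assert s[col].iloc[0] == pytest.approx(np.percentile(vals, q))

    def test_flagging(self):
        s = weight_diagnostics(pd.DataFrame({"weight": np.full(10, 1.5)}))
        assert s["flagged"].iloc[0]
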