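import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit

from pafkit import (
    CohortTable,
    RiskFactorSpec,
    fit_model,
    predict_counterfactual,
    recalibrate_to_prevalence,
)


class TestBinomialFits:
    def test_intercept_only_predicts_mean(self):
        df = pd.DataFrame({"y": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]})
        t = CohortTable(df, outcome="y")
        m = fit_model(t, "y ~ 1", "binomial_logit")
        assert np.allclose(m.predict(df), 0.3)

    def test_saturated_fit(self, saturated_toy):
        m = fit_model(saturated_toy, "y ~ a", "binomial_logit")
        p = m.predict(saturated_toy.df)
        assert p[saturated_toy.df.a == 1][0] == pytest.approx(0.8, abs=1e-8)
        assert p[saturated_toy.df.a == 0][0] == pytest.approx(0.4, abs=1e-8)

    def test_weighted_fit_moves_estimate(self):
        df = pd.DataFrame({"y": [1, 0, 1, 0], "w": [3.0, 1.0, 3.0, 1.0]})
        t = CohortTable(df, outcome="y")
        m = fit_model(t, "y ~ 1", "binomial_logit", weights="w")
        assert m.predict(df)[0] == pytest.approx(0.75, abs=1e-8)

    def test_log_link_predictions_clipped(self):
        df = pd.DataFrame({"y": [1, 0, 0, 0, 1, 0], "x": [0.1, 0, 0, 0.2, 0.3, 0]})
        t = CohortTable(df, outcome="y")
        m = fit_model(t, "y ~ x", "binomial_log")
        assert (m.predict(df) <= 1).all() and (m.predict(df) >= 0).all()


class TestLinearFits:
    def test_exact_line_zero_residuals(self):
        df = pd.DataFrame({"x": [0.0, 1, 2, 3]})
        df["y"] = 2 * df.x + 1
        t = CohortTable(pd.DataFrame({"y01": [0, 1, 0, 1], **df}), outcome="y01")
        m = fit_model(t, "y ~ x", "linear")
        assert np.allclose(m.residuals, 0, atol=1e-10)


class TestCounterfactualPrediction:
    def test_empty_assignment_is_identity(self, saturated_toy):
        m = fit_model(saturated_toy, "y ~ a", "binomial_logit")
        assert np.allclose(
            predict_counterfactual(m, saturated_toy, {}),
            m.predict(saturated_toy.df),
        )

    def test_observed_assignment_is_identity(self, saturated_toy):
        m = fit_model(saturated_toy, "y ~ a", "binomial_logit")
        a_obs = saturated_toy.df["a"].to_numpy()
        assert np.allclose(
            predict_counterfactual(m, saturated_toy, {"a": a_obs}),
            m.predict(saturated_toy.df),
        )

    def test_zero_coefficient_unchanged(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": rng.integers(0, 2, 100), "a": rng.integers(0, 2, 100)})
        t = CohortTable(df, outcome="y")
        m = fit_model(t, "y ~ a", "binomial_logit")
        m.params[1] = 0.0  # null the risk factor effect
        assert np.allclose(
            predict_counterfactual(m, t, {"a": 0}), m.predict(df)
        )

    def test_saturated_counterfactual_constant(self, saturated_toy):
        m = fit_model(saturated_toy, "y ~ a", "binomial_logit")
        p0 = predict_counterfactual(m, saturated_toy, {"a": 0})
        assert np.allclose(p0, 0.4, atol=1e-8)

    def test_original_table_untouched(self, saturated_toy):
        m = fit_model(saturated_toy, "y ~ a", "binomial_logit")
        before = saturated_toy.df.copy()
        predict_counterfactual(m, saturated_toy, {"a": 0})
        pd.testing.assert_frame_equal(saturated_toy.df, before)

    def test_unknown_category_level_errors(self):
        df = pd.DataFrame({"y": [0, 1, 0, 1], "g": pd.Categorical(["a", "b", "a", "b"])})
        t = CohortTable(df, outcome="y")
        m = fit_model(t, "y ~ g", "binomial_logit")
        with pytest.raises(ValueError, match="not level"):
            predict_counterfactual(m, t, {"g": "zzz"})


class TestRecalibration:
    def test_zero_offset_when_already_calibrated(self, saturated_toy):
        m = fit_model(saturated_toy, "y ~ a", "binomial_logit")
        off = recalibrate_to_prevalence(m, saturated_toy, None, 0.6)
        assert off == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_closed_form(self):
        df = pd.DataFrame({"y": [1, 1, 0, 0]})
        t = CohortTable(df, outcome="y")
        m = fit_model(t, "y ~ 1", "binomial_logit")
        off = recalibrate_to_prevalence(m, t, None, 0.25)
        assert off == pytest.approx(math.log(1 / 3) - 0.0, abs=1e-9)

    def test_postcondition_weighted_mean(self, saturated_toy):
        m = fit_model(saturated_toy, "y ~ a", "binomial_logit")
        w = np.linspace(1, 2, saturated_toy.n)
        recalibrate_to_prevalence(m, saturated_toy, w, 0.21)
        p = m.predict(saturated_toy.df)
        assert np.average(p, weights=w) == pytest.approx(0.21, abs=1e-8)

    def test_unachievable_prevalence_rejected(self):
        df = pd.DataFrame({"y": [0, 1]})
        t = CohortTable(df, outcome="y")
        m = fit_model(t, "y ~ 1", "binomial_logit")
        m.params[:] = 0.0
        # achievable range of expit(0 + c) over c in [-100, 100] covers (0,1);
        # the error path needs prevalence outside (0,1), caught earlier
        with pytest.raises(ValueError):
            recalibrate_to_prevalence(m, t, None, 1.2)

    @pytest.mark.parametrize("target", [0.05, 0.3, 0.7])
    def test_root_uniqueness_by_monotonicity(self, saturated_toy, target):
        m = fit_model(saturated_toy, "y ~ a", "binomial_logit")
        off = recalibrate_to_prevalence(m, saturated_toy, None, target)
        lp = m.design_matrix(saturated_toy.df) @ m.params
        grid = np.linspace(-20, 20, 2001)
        gap = np.array([expit(lp + c).mean() - target for c in grid])
        crossings = np.sum(np.diff(np.sign(gap)) != 0)
        assert crossings == 1
        assert gap[np.argmin(np.abs(grid - off))] == pytest.approx(0, abs=1e-3)


class TestConditionalLogit:
    def test_matches_pair_difference_logistic(self):
        # 1:1 matched conditional logistic == logistic on within-pair
        # differences with no intercept (classical equivalence); brute-force
        # the 1-d likelihood by golden search as an independent oracle.
        rng = np.random.default_rng(4)
        n_pairs = 60
        x = rng.standard_normal((n_pairs, 2))
        beta = 0.7
        # case is index 0 in each pair
        rows, ys, ss = [], [], []
        for i in range(n_pairs):
            rows.extend(x[i])
            ys.extend([1, 0])
            ss.extend([i, i])
        df = pd.DataFrame({"y": ys, "x": rows, "s": ss})
        t = CohortTable(df, outcome="y", strata="s")
        m = fit_model(t, "y ~ x", "conditional_logit")
        d = x[:, 0] - x[:, 1]

        def nll(b):
            return np.sum(np.log1p(np.exp(-b * d)))

        b_hat = minimize_scalar(nll, bounds=(-5, 5), method="bounded").x
        got = m.params[list(m.design_info.column_names).index("x")]
        assert got == pytest.approx(b_hat, abs=1e-4)

    def test_requires_strata(self, saturated_toy):
        with pytest.raises(ValueError, match="strata"):
            fit_model(saturated_toy, "y ~ a", "conditional_logit")


class TestCoxToyOracle:
    """6-subject toy: from-scratch partial likelihood + Breslow baseline."""

    @pytest.fixture
    def toy(self):
        df = pd.DataFrame({
            "y": [1, 0, 1, 0, 1, 0],
            "a": [1.0, 0.0, 1.0, 0.0, 0.0, 1.0],
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 1, 0],
        })
        return CohortTable(df, outcome="y", time="time", event="event",
                           risk_factors=[RiskFactorSpec("a", 0)])

    def _oracle(self, toy):
        t = toy.df.time.to_numpy()
        e = toy.df.event.to_numpy()
        a = toy.df.a.to_numpy()

        def neg_pl(b):
            out = 0.0
            for i in range(len(t)):
                if e[i] == 1:
                    risk = t >= t[i]
                    out -= b * a[i] - np.log(np.sum(np.exp(b * a[risk])))
            return out

        b_hat = minimize_scalar(neg_pl, bounds=(-10, 10), method="bounded").x
        # Breslow baseline at b_hat
        H = {}
        acc = 0.0
        for i in np.argsort(t):
            if e[i] == 1:
                acc += 1.0 / np.sum(np.exp(b_hat * a[t >= t[i]]))
            H[t[i]] = acc
        return b_hat, H

    def test_coefficient_matches_partial_likelihood(self, toy):
        m = fit_model(toy, "y ~ a", "prop_hazards")
        b_hat, _ = self._oracle(toy)
        idx = list(m.design_info.column_names).index("a")
        assert m.params[idx] == pytest.approx(b_hat, abs=1e-4)

    def test_baseline_cumhaz_matches_breslow(self, toy):
        m = fit_model(toy, "y ~ a", "prop_hazards")
        b_hat, H = self._oracle(toy)
        for t_ev in [1.0, 2.0, 4.0, 5.0]:
            _, got = m.extras.nearest_event_time(t_ev)
            assert got == pytest.approx(H[t_ev], rel=1e-3)

    def test_eq7_matches_hand_computation(self, toy):
        from pafkit import paf_survival

        m = fit_model(toy, "y ~ a", "prop_hazards")
        b_hat, H = self._oracle(toy)
        a = toy.df.a.to_numpy()
        # hazard ratios centred as the package reports them (binary col -> 0)
        r_obs = np.exp(b_hat * a)
        r_ref = np.ones_like(a)
        for t_ev in [2.0, 5.0]:
            H0 = H[t_ev]
            num = np.sum(np.exp(-H0 * r_ref) - np.exp(-H0 * r_obs))
            den = np.sum(1 - np.exp(-H0 * r_obs))
            expected = num / den
            got = paf_survival(m, toy, "a", [t_ev]).estimate[0]
            assert got == pytest.approx(expected, rel=1e-3)


class TestOrdinalLogit:
    def test_matches_statsmodels_unweighted(self):
        rng = np.random.default_rng(3)
        n = 400
        x = rng.standard_normal(n)
        latent = 0.8 * x + rng.logistic(size=n)
        y = np.digitize(latent, [-0.5, 0.9]).astype(int)
        df = pd.DataFrame({"y01": rng.integers(0, 2, n), "grade": y, "x": x})
        t = CohortTable(df, outcome="y01")
        m = fit_model(t, "grade ~ x", "ordinal_logit")
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        om = OrderedModel(y, x[:, None], distr="logit").fit(disp=False, method="bfgs")
        idx = list(m.design_info.column_names).index("x")
        assert m.params[idx] == pytest.approx(float(np.asarray(om.params)[0]), abs=1e-4)

    def test_category_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "y01": rng.integers(0, 2, 200),
            "grade": rng.integers(0, 3, 200),
            "x": rng.standard_normal(200),
        })
        t = CohortTable(df, outcome="y01")
        m = fit_model(t, "grade ~ x", "ordinal_logit")
        probs = m.predict(df)
        assert np.allclose(probs.sum(axis=1), 1.0)


def test_unknown_family_rejected(saturated_toy):
    with pytest.raises(ValueError, match="unknown family"):
        fit_model(saturated_toy, "y ~ a", "poisson")


def test_convergence_failure_mentions_family_and_formula():
    df = pd.DataFrame({"y": [0, 1, 0, 1], "x": [1.0, 1.0, 1.0, 1.0]})
    t = CohortTable(df, outcome="y")
    try:
        fit_model(t, "y ~ 0 + x", "linear")
    except RuntimeError as err:
        assert "linear" in str(err) and "y ~ 0 + x" in str(err)
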