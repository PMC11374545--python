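import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

from conftest import degenerate_design, make_design
from oracles import naive_jackknife_variance
from plantdex.survey_inference import (
    CollinearityError,
    DegenerateTestError,
    DesignError,
    MODEL_LADDER,
    ModelSpec,
    SeparationError,
    SurveyDesign,
    categorical_test,
    fit_survey_glm,
    trend_test,
    weighted_mean,
)


class TestWeightedMean:
    def test_degenerate_replicates_zero_se(self):
        d = degenerate_design(10)
        est, se = weighted_mean(np.arange(10.0), d)
        assert est == pytest.approx(4.5)
        assert se == 0.0

    def test_hand_computed_weighted_mean(self):
        d = degenerate_design(2)
        d.weights = np.array([1.0, 3.0])
        d.rep_weights = np.tile(d.weights[:, None], (1, 4))
        est, _ = weighted_mean(np.array([1.0, 3.0]), d)
        assert est == pytest.approx(2.5)

    def test_weight_scale_invariance(self):
        d = make_design(30, seed=2)
        x = np.random.default_rng(0).normal(0, 1, 30)
        est1, _ = weighted_mean(x, d)
        d2 = SurveyDesign(d.ids, 10 * d.weights, 10 * d.rep_weights, d.variance_factor)
        est2, _ = weighted_mean(x, d2)
        assert est1 == pytest.approx(est2)

    def test_replicate_variance_matches_naive_loop(self):
        d = make_design(47, seed=9, R=12)
        x = np.random.default_rng(3).normal(5, 2, 47)

        def stat(w):
            return float((w * x).sum() / w.sum())

        _, se = weighted_mean(x, d)
        var = naive_jackknife_variance(stat, d.weights, d.rep_weights, d.variance_factor)
        assert se**2 == pytest.approx(var, rel=1e-12)

    def test_misaligned_values_rejected(self):
        with pytest.raises(DesignError):
            weighted_mean(np.ones(5), make_design(6))


class TestSurveyGlm:
    def test_linear_equal_weights_matches_ols(self, regression_frame):
        """Equal weights + degenerate replicates reduce the survey fit to
        ordinary least squares, with zero replicate SEs."""
        d = degenerate_design(len(regression_frame))
        spec = ModelSpec("y", "linear", ["x1", "x2"])
        res = fit_survey_glm(regression_frame, spec, d)
        X = sm.add_constant(regression_frame[["x1", "x2"]])
        ols = sm.OLS(regression_frame["y"], X).fit()
        np.testing.assert_allclose(res.params, ols.params.to_numpy(), atol=1e-10)
        assert np.all(res.se == 0.0)

    def test_logistic_equal_weights_matches_mle(self, regression_frame):
        d = degenerate_design(len(regression_frame))
        spec = ModelSpec("yb", "logistic", ["x1"])
        res = fit_survey_glm(regression_frame, spec, d)
        X = sm.add_constant(regression_frame[["x1"]])
        mle = sm.Logit(regression_frame["yb"], X).fit(disp=0)
        np.testing.assert_allclose(res.params, mle.params.to_numpy(), atol=1e-6)

    def test_intercept_only_logistic_is_logit_prevalence(self):
        y = np.array([1.0] * 3 + [0.0] * 7)
        df = pd.DataFrame({"y": y})
        d = degenerate_design(10)
        res = fit_survey_glm(df, ModelSpec("y", "logistic", []), d)
        assert res.params[0] == pytest.approx(np.log(0.3 / 0.7), abs=1e-7)

    def test_log_outcome_transform(self, regression_frame):
        df = regression_frame.assign(ypos=np.exp(regression_frame["y"] / 4))
        d = degenerate_design(len(df))
        res = fit_survey_glm(df, ModelSpec("ypos", "linear", ["x1"], log_outcome=True), d)
        direct = fit_survey_glm(
            df.assign(ypos=np.log(df["ypos"])), ModelSpec("ypos", "linear", ["x1"]), d
        )
        np.testing.assert_allclose(res.params, direct.params)

    def test_ci_brackets_estimate_and_or_is_exp(self):
        rng = np.random.default_rng(11)
        n = 120
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-0.5 * x))).astype(float)
        df = pd.DataFrame({"x": x, "y": y})
        d = make_design(n, seed=1, R=10)
        res = fit_survey_glm(df, ModelSpec("y", "logistic", ["x"]), d)
        ci = res.ci95
        assert np.all(ci[:, 0] <= res.params) and np.all(res.params <= ci[:, 1])
        np.testing.assert_allclose(res.odds_ratios, np.exp(res.params))

    def test_or_monotone_in_coefficient(self):
        rng = np.random.default_rng(12)
        n = 150
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-1.0 * x))).astype(float)
        d = degenerate_design(n)
        up = fit_survey_glm(pd.DataFrame({"x": x, "y": y}),
                            ModelSpec("y", "logistic", ["x"]), d)
        down = fit_survey_glm(pd.DataFrame({"x": -x, "y": y}),
                              ModelSpec("y", "logistic", ["x"]), d)
        assert up.term("x")["odds_ratio"] > 1 > down.term("x")["odds_ratio"]
        assert up.term("x")["estimate"] == pytest.approx(-down.term("x")["estimate"])

    def test_perfect_separation_raises(self):
        x = np.linspace(-2, 2, 20)
        y = (x > 0).astype(float)
        df = pd.DataFrame({"x": x, "y": y})
        with pytest.raises(SeparationError, match="x"):
            fit_survey_glm(df, ModelSpec("y", "logistic", ["x"]), degenerate_design(20))

    def test_collinearity_raises(self, regression_frame):
        df = regression_frame.assign(x3=2 * regression_frame["x1"])
        with pytest.raises(CollinearityError):
            fit_survey_glm(
                df, ModelSpec("y", "linear", ["x1", "x3"]),
                degenerate_design(len(df)),
            )

    def test_categorical_covariates_expand_to_dummies(self):
        rng = np.random.default_rng(13)
        n = 60
        df = pd.DataFrame(
            {
                "y": rng.normal(0, 1, n),
                "edu": rng.choice(["low", "medium", "high"], n),
            }
        )
        res = fit_survey_glm(df, ModelSpec("y", "linear", ["edu"]), degenerate_design(n))
        assert res.terms == ["intercept", "edu[low]", "edu[medium]"]

    def test_model_ladder_covariate_sets(self):
        assert MODEL_LADDER["M1"] == ["age", "sex"]
        assert MODEL_LADDER["fig2"] == [
            "age", "sex", "energy_kj", "education", "physical_activity",
            "smoking", "diabetes", "hypertension", "bmi", "alcohol",
        ]
        spec = ModelSpec.from_ladder("M5", "bmi", exposure="pdi")
        assert "bmi" not in spec.covariates  # BMI outcome not BMI-adjusted
        spec2 = ModelSpec.from_ladder("M5", "hdl", exposure="pdi")
        assert "bmi" in spec2.covariates


class TestTrendTest:
    def _frame(self, n=200, slope=1.0, seed=0):
        rng = np.random.default_rng(seed)
        q = rng.integers(1, 6, n)
        y = slope * q + 0.01 * rng.normal(0, 1, n)
        return pd.DataFrame({"y": y, "q": q})

    def test_perfect_trend_tiny_p(self):
        df = self._frame()
        p = trend_test(df, "y", "q", make_design(len(df), seed=4))
        assert p < 1e-10

    def test_reversed_quintiles_flip_sign_same_p(self):
        df = self._frame(seed=5)
        d = make_design(len(df), seed=5)
        spec = lambda frame: fit_survey_glm(  # noqa: E731
            frame.assign(_trend=frame["q"].astype(float)),
            ModelSpec("y", "linear", [], exposure="_trend"), d,
        ).term("_trend")
        fwd = spec(df)
        rev = spec(df.assign(q=6 - df["q"]))
        assert fwd["estimate"] == pytest.approx(-rev["estimate"], rel=1e-9)
        assert fwd["p"] == pytest.approx(rev["p"], rel=1e-9, abs=1e-300)

    def test_constant_outcome_degenerate(self):
        df = pd.DataFrame({"y": np.ones(50), "q": np.tile(np.arange(1, 6), 10)})
        with pytest.raises(DegenerateTestError):
            trend_test(df, "y", "q", make_design(50))


class TestCategoricalTest:
    def test_perfect_independence_2x2(self):
        a = ["x"] * 50 + ["y"] * 50
        b = (["u"] * 25 + ["v"] * 25) * 2
        stat, dof, p = categorical_test(a, b, degenerate_design(100))
        assert stat == pytest.approx(0.0)
        assert dof == 1
        assert p == pytest.approx(1.0)

    def test_equal_weights_matches_textbook_chi2(self):
        rng = np.random.default_rng(21)
        a = rng.choice(["a", "b", "c"], 120)
        b = rng.choice(["u", "v"], 120)
        stat, dof, p = categorical_test(a, b, degenerate_design(120))
        tab = pd.crosstab(pd.Series(a), pd.Series(b))
        want = scipy.stats.chi2_contingency(tab, correction=False)
        assert stat == pytest.approx(want.statistic, rel=1e-9)
        assert p == pytest.approx(want.pvalue, rel=1e-6)

    def test_design_effect_shrinks_statistic_with_unequal_weights(self):
        rng = np.random.default_rng(22)
        n = 200
        a = rng.choice(["a", "b"], n)
        b = rng.choice(["u", "v"], n)
        d = make_design(n, seed=22, R=20)
        stat_corr, _, _ = categorical_test(a, b, d, correction=True)
        stat_raw, _, _ = categorical_test(a, b, d, correction=False)
        assert stat_corr != stat_raw  # correction engaged

    def test_single_level_degenerate(self):
        with pytest.raises(DegenerateTestError):
            categorical_test(["x"] * 10, ["u", "v"] * 5, degenerate_design(10))
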