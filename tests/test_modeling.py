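"""OLS, AICc selection and the regression diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from phenoanomaly import (
    AnalysisError,
    all_subsets_selection,
    compare_linear_quadratic,
    fit_ols,
    leave_one_covariate_residual_check,
    partial_r2,
    residual_diagnostics,
    stepwise_backward,
    vif,
)
from phenoanomaly.modeling import (
    aicc_from_aic,
    choose_functional_form,
    gaussian_loglik,
)


def design(rng, n, p, names=None):
    names = names or [f"x{i + 1}" for i in range(p)]
    return pd.DataFrame(rng.normal(size=(n, p)), columns=names)


class TestFitOls:
    def test_exact_fit_recovers_coefficient(self):
        x = np.arange(1.0, 8.0)
        fm = fit_ols(2 * x, pd.DataFrame({"x": x}))
        assert fm.params["x"] == pytest.approx(2.0)
        assert fm.r_squared == pytest.approx(1.0)
        np.testing.assert_allclose(fm.residuals, 0.0, atol=1e-10)

    def test_independent_noise_has_small_t(self):
        rng = np.random.default_rng(0)
        X = design(rng, 500, 1)
        fm = fit_ols(rng.normal(size=500), X)
        assert abs(fm.tvalues["x1"]) < 3
        assert fm.r_squared < 0.03

    def test_duplicate_column_is_a_rank_error(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(AnalysisError, match="collinear"):
            fit_ols(x + 1, X)

    def test_too_small_sample_is_an_error(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 1.0]})
        with pytest.raises(AnalysisError, match="too small"):
            fit_ols(np.array([1.0, 2.0]), X)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        """Small-n fits agree with the explicit (X'X)^-1 X'y solution."""
        rng = np.random.default_rng(seed)
        n, p = 10, 3
        X = design(rng, n, p)
        y = rng.normal(size=n)
        fm = fit_ols(y, X)
        A = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(fm.params.to_numpy(), beta, rtol=1e-10)

    def test_residuals_sum_to_zero_with_intercept(self):
        rng = np.random.default_rng(1)
        fm = fit_ols(rng.normal(size=30), design(rng, 30, 2))
        assert fm.residuals.sum() == pytest.approx(0.0, abs=1e-9)


class TestAicc:
    def test_formula_arithmetic(self):
        # AIC 100, k 5, n 34 -> 100 + 2*5*6/28
        assert aicc_from_aic(100.0, 5, 34) == pytest.approx(100 + 60 / 28)
        assert aicc_from_aic(100.0, 5, 34) == pytest.approx(102.142857, abs=1e-6)

    def test_large_n_limit_approaches_aic(self):
        assert aicc_from_aic(100.0, 5, 10**9) == pytest.approx(100.0, abs=1e-6)

    def test_too_many_parameters_is_an_error(self):
        with pytest.raises(AnalysisError):
            aicc_from_aic(10.0, 10, 11)

    def test_model_aicc_uses_full_parameter_count(self):
        rng = np.random.default_rng(2)
        X = design(rng, 34, 2)
        y = rng.normal(size=34)
        fm = fit_ols(y, X)
        k = 4  # intercept + 2 slopes + residual variance
        aic = -2 * gaussian_loglik(fm.rss, 34) + 2 * k
        assert fm.aicc == pytest.approx(aicc_from_aic(aic, k, 34))

    def test_noise_covariate_usually_raises_aicc(self):
        rng = np.random.default_rng(3)
        worse = 0
        for _ in range(20):
            X = design(rng, 34, 2)
            y = 1.5 * X["x1"] + rng.normal(size=34)
            small = fit_ols(y, X, ("x1",))
            big = fit_ols(y, X, ("x1", "x2"))
            worse += big.aicc > small.aicc
        assert worse >= 13


class TestVif:
    def test_orthogonal_columns_have_unit_vif(self):
        X = pd.DataFrame(
            {"a": [1, 1, -1, -1], "b": [1, -1, 1, -1], "c": [1, -1, -1, 1]},
            dtype=float,
        )
        np.testing.assert_allclose(vif(X).to_numpy(), 1.0, atol=1e-12)

    def test_two_columns_closed_form(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=50)
        b = 0.6 * a + rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": b})
        r = np.corrcoef(a, b)[0, 1]
        np.testing.assert_allclose(vif(X).to_numpy(), 1 / (1 - r**2), rtol=1e-10)

    def test_perfect_collinearity_is_an_error(self):
        x = np.arange(10.0)
        with pytest.raises(AnalysisError, match="collinear|infinite"):
            vif(pd.DataFrame({"a": x, "b": 2 * x}))


class TestAllSubsets:
    def test_dominant_signal_selects_the_signal_only(self):
        rng = np.random.default_rng(5)
        exact = 0
        for _ in range(10):
            X = design(rng, 40, 2)
            y = X["x1"].to_numpy() + rng.normal(0, 0.05, size=40)
            res = all_subsets_selection(y, X)
            assert "x1" in res.best.terms  # the signal is never missed
            exact += res.best.terms == ("x1",)
        assert exact >= 6  # noise term only enters occasionally

    def test_ledger_enumerates_every_subset(self):
        rng = np.random.default_rng(6)
        X = design(rng, 30, 5)
        res = all_subsets_selection(rng.normal(size=30), X)
        assert len(res.ledger) + len(res.skipped) == 2**5
        assert res.ledger["delta_aicc"].min() == 0.0
        assert res.ledger["aicc"].is_monotonic_increasing

    def test_fourteen_candidates_give_16384_models(self):
        rng = np.random.default_rng(7)
        X = design(rng, 36, 14)
        res = all_subsets_selection(rng.normal(size=36), X)
        assert len(res.ledger) == 2**14

    def test_pure_noise_usually_selects_intercept_only(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(15):
            X = design(rng, 34, 3)
            res = all_subsets_selection(rng.normal(size=34), X)
            hits += res.best.terms == ()
        assert hits >= 8

    def test_subset_rss_matches_statsmodels(self):
        """Dual route: the batched Gram-matrix RSS equals statsmodels OLS."""
        rng = np.random.default_rng(9)
        X = design(rng, 25, 4)
        y = rng.normal(size=25)
        res = all_subsets_selection(y, X)
        for _, row in res.ledger.sample(6, random_state=0).iterrows():
            terms = row["terms"]
            A = sm.add_constant(X[list(terms)].to_numpy()) if terms else np.ones((25, 1))
            ref = sm.OLS(y, A).fit()
            k = len(terms) + 2
            aic = -2 * ref.llf + 2 * k
            assert row["aicc"] == pytest.approx(aicc_from_aic(aic, k, 25), rel=1e-9)

    def test_deterministic_ledger_order(self):
        rng = np.random.default_rng(10)
        X = design(rng, 30, 4)
        y = rng.normal(size=30)
        a = all_subsets_selection(y, X)
        b = all_subsets_selection(y, X)
        assert list(a.ledger["terms"]) == list(b.ledger["terms"])


class TestStepwiseBackward:
    def test_agrees_with_all_subsets_on_strong_signal(self):
        rng = np.random.default_rng(11)
        X = design(rng, 40, 4)
        y = 2.0 * X["x2"].to_numpy() + rng.normal(0, 0.3, size=40)
        sw = stepwise_backward(y, X)
        asub = all_subsets_selection(y, X)
        assert set(sw.best.terms) == set(asub.best.terms) == {"x2"}

    def test_full_model_is_a_fixed_point_when_all_terms_matter(self):
        rng = np.random.default_rng(12)
        X = design(rng, 60, 3)
        y = (X @ np.array([2.0, -2.0, 2.0])).to_numpy() + rng.normal(0, 0.2, size=60)
        sw = stepwise_backward(y, X)
        assert set(sw.best.terms) == {"x1", "x2", "x3"}
        assert sw.path[0] == ("<full>", pytest.approx(sw.path[0][1]))

    def test_elimination_path_is_reproducible(self):
        rng = np.random.default_rng(13)
        X = design(rng, 40, 5)
        y = X["x1"].to_numpy() + rng.normal(size=40)
        a = stepwise_backward(y, X)
        b = stepwise_backward(y, X)
        assert a.path == b.path


class TestPartialR2:
    def test_perfect_term_explains_everything(self):
        x = np.arange(12.0)
        rng = np.random.default_rng(14)
        X = pd.DataFrame({"x1": x, "x2": rng.normal(size=12)})
        fm = fit_ols(3 * x, X, ("x1", "x2"))
        pr2 = partial_r2(fm, X, 3 * x)
        assert pr2["x1"] == pytest.approx(1.0)

    def test_irrelevant_term_near_zero(self):
        rng = np.random.default_rng(15)
        X = design(rng, 400, 2)
        y = X["x1"].to_numpy() + rng.normal(size=400)
        fm = fit_ols(y, X)
        assert partial_r2(fm, X, y)["x2"] < 0.02

    def test_equals_drop_one_refit_brute_force(self):
        rng = np.random.default_rng(16)
        X = design(rng, 20, 3)
        y = rng.normal(size=20)
        fm = fit_ols(y, X)
        pr2 = partial_r2(fm, X, y)
        A_full = np.column_stack([np.ones(20), X.to_numpy()])
        rss_full = float(np.sum((y - A_full @ np.linalg.lstsq(A_full, y, rcond=None)[0]) ** 2))
        for i, term in enumerate(X.columns):
            A_red = np.delete(A_full, i + 1, axis=1)
            rss_red = float(np.sum((y - A_red @ np.linalg.lstsq(A_red, y, rcond=None)[0]) ** 2))
            ss = rss_red - rss_full
            assert pr2[term] == pytest.approx(ss / (ss + rss_full), rel=1e-9)


class TestLinearVsQuadratic:
    def test_truly_quadratic_signal_prefers_quadratic(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=40)
        y = x**2 + rng.normal(0, 0.05, size=40)
        assert compare_linear_quadratic(y, x).choice == "quadratic"

    def test_linear_signal_keeps_linear_form(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(0, 0.05, size=40)
        assert compare_linear_quadratic(y, x).choice == "linear"

    @pytest.mark.parametrize(
        "delta, expected",
        [(-1.5, "linear"), (-2.0, "linear"), (-2.5, "quadratic"), (3.0, "linear")],
    )
    def test_decision_threshold(self, delta, expected):
        assert choose_functional_form(delta) == expected


class TestLeaveOneCovariate:
    def test_true_effects_show_matching_residual_slopes(self):
        rng = np.random.default_rng(19)
        X = design(rng, 60, 3)
        y = (X @ np.array([-0.5, -0.5, 0.0])).to_numpy() + rng.normal(0, 0.3, size=60)
        table = leave_one_covariate_residual_check(y, X, ("x1", "x2", "x3"))
        s = table.set_index("term")
        assert s.loc["x1", "slope"] < 0 and s.loc["x1", "p"] < 0.05
        assert s.loc["x2", "slope"] < 0 and s.loc["x2", "p"] < 0.05
        assert abs(s.loc["x3", "slope"]) < 0.2

    def test_single_term_model_is_an_error(self):
        rng = np.random.default_rng(20)
        X = design(rng, 30, 1)
        with pytest.raises(AnalysisError):
            leave_one_covariate_residual_check(rng.normal(size=30), X, ("x1",))


class TestResidualDiagnostics:
    def test_exact_fit_is_flagged_degenerate(self):
        x = np.arange(10.0)
        fm = fit_ols(2 * x + 1, pd.DataFrame({"x": x}))
        assert residual_diagnostics(fm).degenerate

    def test_gaussian_errors_rarely_rejected(self):
        rng = np.random.default_rng(21)
        rejected = 0
        for _ in range(100):
            X = design(rng, 34, 2)
            y = X["x1"].to_numpy() + rng.normal(size=34)
            d = residual_diagnostics(fit_ols(y, X))
            rejected += d.normality_p < 0.05
        assert rejected <= 10

    def test_heavy_tailed_errors_usually_rejected(self):
        rng = np.random.default_rng(22)
        rejected = 0
        for _ in range(30):
            X = design(rng, 34, 2)
            y = X["x1"].to_numpy() + rng.standard_cauchy(size=34)
            d = residual_diagnostics(fit_ols(y, X))
            rejected += d.normality_p < 0.05
        assert rejected >= 16
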