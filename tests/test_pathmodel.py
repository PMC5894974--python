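"""Path-model specification, ML fitting, and derived quantities."""

import numpy as np
import pytest
from scipy import optimize

import pathprog as pp
from pathprog.moments import MomentSet
from pathprog.pathmodel import (
    _implied_cov,
    _iterative_fit,
    adjusted_r2,
    ml_discrepancy,
)


class TestDegreesOfFreedom:
    def test_saturated_zero(self):
        spec = pp.PathModelSpec(["y1", "y2"], ["x1", "x2"])
        assert pp.count_degrees_of_freedom(spec) == 0

    def test_hand_counted_single_constraint(self):
        # p=5 -> 15 moments; exogenous 6 + paths 5 + residual 3 = 14 free
        spec = pp.PathModelSpec(["y1", "y2"], ["x1", "x2", "x3"],
                                {("x3", "y2")})
        assert pp.count_degrees_of_freedom(spec) == 1

    def test_final_study_structure(self):
        spec = pp.final_model_spec()
        assert spec.k_total == 21 and spec.q == 7
        assert pp.count_degrees_of_freedom(spec) == 77


class TestFitML:
    def test_saturated_equals_least_squares(self, toy_moments):
        spec = pp.PathModelSpec(["y1", "y2"], ["x1", "x2"])
        fit = pp.fit_ml(toy_moments, spec)
        S = toy_moments.cov
        b_ols = np.linalg.solve(S[:2, :2], S[:2, 2:])
        assert fit.F_ML == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.b, b_ols, atol=1e-12)

    def test_single_standardized_predictor_equals_r(self):
        ms = MomentSet(["x", "y"], 383, np.zeros(2), np.ones(2),
                       np.array([[1, 0.79], [0.79, 1.0]]))
        fit = pp.fit_ml(ms, pp.PathModelSpec(["y"], ["x"]))
        assert fit.b[0, 0] == pytest.approx(0.79)
        assert fit.B[0, 0] == pytest.approx(0.79)

    def test_iterative_matches_independent_minimizer(self, toy_moments):
        spec = pp.PathModelSpec(["y1", "y2"], ["x1", "x2"], {("x2", "y1")})
        fit = pp.fit_ml(toy_moments, spec)
        assert fit.method == "iterative"
        S = toy_moments.cov

        def oracle(t):  # free params: b11, b12, b22, psi (3)
            b = np.array([[t[0], t[1]], [0.0, t[2]]])
            psi = np.array([[t[3], t[4]], [t[4], t[5]]])
            try:
                return ml_discrepancy(S, _implied_cov(S[:2, :2], b, psi))
            except np.linalg.LinAlgError:
                return np.inf

        res = optimize.minimize(
            oracle, [0.3, 0.1, 0.4, 0.8, 0.1, 0.8], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 40000},
        )
        assert fit.F_ML == pytest.approx(res.fun, abs=1e-4)
        assert fit.b[0, 0] == pytest.approx(res.x[0], abs=1e-4)

    def test_iterative_equals_closed_form_on_equal_regressors(self, toy_moments):
        # mandatory internal cross-check: same spec through both branches
        spec = pp.PathModelSpec(["y1", "y2"], ["x1", "x2"],
                                {("x2", "y1"), ("x2", "y2")})
        closed = pp.fit_ml(toy_moments, spec)
        assert closed.method == "closed_form"
        b_it, psi_it, _, _ = _iterative_fit(toy_moments.cov, spec)
        assert np.allclose(closed.b, b_it, atol=1e-6)
        assert np.allclose(closed.psi, psi_it, atol=1e-6)

    def test_reconstruction_consistency(self, toy_moments):
        # saturated model's implied covariance reproduces the sample exactly
        fit = pp.fit_ml(toy_moments, pp.PathModelSpec(["y1", "y2"], ["x1", "x2"]))
        assert np.allclose(fit.implied_cov, toy_moments.cov, atol=1e-10)

    def test_scale_equivariance(self, toy_moments):
        spec = pp.PathModelSpec(["y1", "y2"], ["x1", "x2"])
        fit = pp.fit_ml(toy_moments, spec)
        scaled = MomentSet(toy_moments.names, toy_moments.n,
                           toy_moments.means, toy_moments.sds * [3.0, 1, 1, 1],
                           toy_moments.corr)
        fit_s = pp.fit_ml(scaled, spec)
        assert np.allclose(fit_s.b[0], fit.b[0] / 3.0)
        assert np.allclose(fit_s.B, fit.B, atol=1e-12)

    def test_non_pd_moments_rejected(self):
        bad = np.full((3, 3), -0.6)
        np.fill_diagonal(bad, 1.0)
        ms = MomentSet(["x", "y1", "y2"], 50, np.zeros(3), np.ones(3), bad)
        with pytest.raises(ValueError, match="repair"):
            pp.fit_ml(ms, pp.PathModelSpec(["y1", "y2"], ["x"]))


class TestStandardize:
    def test_study_cross_check(self):
        # b = 0.40 from baseline trait anxiety (SD 8.1) to day-7 state
        # anxiety (SD 8.9) standardizes to 0.36
        assert round(pp.standardize(0.40, 8.1, 8.9), 2) == 0.36

    def test_zero_and_unit_ratio(self):
        assert pp.standardize(0.0, 2.0, 3.0) == 0.0
        assert pp.standardize(0.7, 2.0, 2.0) == 0.7

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            pp.standardize(1.0, 0.0, 1.0)


class TestExplainedVariance:
    def test_perfect_fit_adjusts_to_one(self):
        assert adjusted_r2(1.0, 383, 10) == pytest.approx(1.0)

    def test_null_model_adjustment(self):
        # r2 = 0, n = 383, k = 10: 1 - 382/372
        assert adjusted_r2(0.0, 383, 10) == pytest.approx(1 - 382 / 372)

    def test_single_predictor_r2(self):
        ms = MomentSet(["x", "y"], 383, np.zeros(2), np.ones(2),
                       np.array([[1, 0.79], [0.79, 1.0]]))
        fit = pp.fit_ml(ms, pp.PathModelSpec(["y"], ["x"]))
        r2, _ = pp.explained_variance(fit, k=1)
        assert r2[0] == pytest.approx(0.79**2)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 11, 10)


class TestWaldPvalues:
    def test_reference_points(self, toy_moments):
        from scipy import stats
        assert 2 * stats.norm.sf(0.0) == 1.0
        fit = pp.fit_ml(toy_moments, pp.PathModelSpec(["y1", "y2"], ["x1", "x2"]))
        z = fit.b / fit.se
        expect = 2 * stats.norm.sf(np.abs(z))
        assert np.allclose(pp.wald_pvalues(fit), expect, equal_nan=True)

    def test_matches_least_squares_t(self):
        """Closed-form SEs agree with the textbook OLS fit on the same data."""
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        n = 2000
        X = rng.standard_normal((n, 2))
        y = 0.4 * X[:, 0] + 0.1 * X[:, 1] + rng.standard_normal(n)
        from .conftest import simple_table
        tab = simple_table(np.column_stack([X, y]), 2, ["x1", "x2", "y1"])
        fit = pp.fit_ml(tab, pp.PathModelSpec(["y1"], ["x1", "x2"]))
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert fit.b[:, 0] == pytest.approx(ols.params[1:], abs=1e-10)
        assert fit.se[:, 0] == pytest.approx(ols.bse[1:], abs=1e-10)


class TestSensitivityAndEffects:
    def test_trait_anxiety_only_model(self, daycase):
        r2 = pp.single_predictor_sensitivity(
            daycase, "t0_stai_trait", ["t1_stai_trait", "t1_stai_state"])
        assert round(r2["t1_stai_trait"], 2) == 0.62
        assert round(r2["t1_stai_state"], 2) == 0.37

    def test_unknown_predictor_rejected(self, daycase):
        with pytest.raises(KeyError):
            pp.single_predictor_sensitivity(daycase, "nope", ["t1_mfi"])

    def test_important_effects_thresholds(self, final_fit):
        hits = pp.important_effects(final_fit, 0.20)
        pairs = {(p, o) for p, o, _ in hits}
        assert ("t0_stai_trait", "t1_stai_trait") in pairs
        assert ("t0_mfi", "t1_mfi") in pairs
        assert pp.important_effects(final_fit, 1.1) == []
        n_free = int(final_fit.spec.free_mask().sum())
        assert len(pp.important_effects(final_fit, 0.0)) == n_free

    def test_effects_sorted_within_outcome(self, final_fit):
        hits = pp.important_effects(final_fit, 0.0)
        by_outcome = {}
        for p, o, B in hits:
            by_outcome.setdefault(o, []).append(abs(B))
        for vals in by_outcome.values():
            assert vals == sorted(vals, reverse=True)


def test_parameter_recovery_large_n():
    """Coefficients fitted on a big simulated cohort match the population
    values implied by the target moments to within 0.02 standardized."""
    cfg = pp.SyntheticConfig(n=100_000, seed=11, missing_rate_t1=0.0,
                             extra_null_predictors=False)
    table = pp.generate_cohort(cfg)
    spec = pp.final_model_spec(include_eliminated=False)
    fit_sim = pp.fit_ml(table, spec)
    fit_pop = pp.fit_ml(pp.daycase_moments(repaired=True), spec)
    assert np.abs(fit_sim.B - fit_pop.B).max() < 0.02
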