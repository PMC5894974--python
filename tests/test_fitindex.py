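"""Chi-square, incremental indices, RMSEA inversion, SRMR, robust scaling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pathprog as pp
from pathprog.moments import MomentSet

from .conftest import simple_table


class TestChiSquare:
    def test_zero_discrepancy(self):
        chi2, p = pp.chi_square_test(0.0, 398, 10)
        assert chi2 == 0.0 and p == 1.0

    def test_saturated_p_is_one(self):
        assert pp.chi_square_test(0.0, 398, 0)[1] == 1.0

    def test_printed_ml_p_value(self):
        # chi2 = 97.36 on 77 df prints P = 0.06
        assert round(float(stats.chi2.sf(97.36, 77)), 2) == 0.06

    def test_printed_ratio(self):
        assert round(98.99 / 77, 2) == 1.29

    def test_negative_discrepancy_rejected(self):
        with pytest.raises(ValueError):
            pp.chi_square_test(-0.1, 100, 5)


class TestBaseline:
    def test_diagonal_moments_fit_perfectly(self):
        ms = MomentSet(["a", "b", "c"], 100, np.zeros(3), np.ones(3), np.eye(3))
        chi2_b, df_b = pp.baseline_model(ms)
        assert chi2_b == pytest.approx(0.0)
        assert df_b == 3

    def test_bivariate_closed_form(self):
        # independence baseline for two variables: chi2 = -(n-1) ln(1-r^2)
        r, n = 0.6, 200
        ms = MomentSet(["a", "b"], n, np.zeros(2), np.ones(2),
                       np.array([[1, r], [r, 1.0]]))
        chi2_b, df_b = pp.baseline_model(ms)
        assert df_b == 1
        assert chi2_b == pytest.approx(-(n - 1) * np.log(1 - r**2))


class TestCfiTli:
    def test_better_than_expected_fit(self):
        cfi, _ = pp.cfi_tli(5.0, 10, 300.0, 45)
        assert cfi == 1.0

    def test_no_improvement_over_baseline(self):
        cfi, tli = pp.cfi_tli(300.0, 45, 300.0, 45)
        assert cfi == 0.0
        assert tli == pytest.approx(0.0)

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(ValueError):
            pp.cfi_tli(10.0, 5, 20.0, 0)


def test_incremental_indices_against_simulated_baseline():
    """With an independence baseline computed from a simulated default
    cohort, the printed chi-square (98.99, df 77) yields CFI ~ 0.99 and
    TLI ~ 0.98 within 0.01."""
    import warnings

    names = pp.daycase_moments().names
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = pp.generate_cohort(pp.SyntheticConfig(seed=0))
        comp, _ = pp.apply_missingness_policy(tab, tab.names)
        ms = pp.compute_moments(comp, names)
    chi2_b, df_b = pp.baseline_model(ms)
    cfi, tli = pp.cfi_tli(98.99, 77, chi2_b, df_b)
    assert cfi == pytest.approx(0.99, abs=0.01)
    assert tli == pytest.approx(0.98, abs=0.011)


class TestRmsea:
    def test_perfect_fit(self):
        point, lo, hi = pp.rmsea_with_ci(5.0, 10, 100)
        assert point == 0.0 and lo == 0.0

    @pytest.mark.parametrize("convention", ["n-1", "n"])
    def test_printed_point_estimate(self, convention):
        point, _, _ = pp.rmsea_with_ci(98.99, 77, 398, convention=convention)
        assert round(point, 2) == 0.03

    def test_printed_confidence_interval(self):
        _, lo, hi = pp.rmsea_with_ci(98.99, 77, 398)
        assert lo == pytest.approx(0.004, abs=0.005)
        assert hi == pytest.approx(0.042, abs=0.005)

    def test_ci_inversion_consistency(self):
        # the lambda behind each bound must reproduce its target probability
        chi2, df, n = 98.99, 77, 398
        _, lo, hi = pp.rmsea_with_ci(chi2, df, n)
        for bound, target in ((lo, 0.95), (hi, 0.05)):
            lam = bound**2 * df * (n - 1)
            if lam > 0:
                assert stats.ncx2.cdf(chi2, df, lam) == pytest.approx(
                    target, abs=1e-6)

    def test_df_zero_rejected(self):
        with pytest.raises(ValueError):
            pp.rmsea_with_ci(1.0, 0, 100)


class TestSrmr:
    def test_perfect_fit(self, toy_moments):
        S = toy_moments.cov
        assert pp.srmr(S, S) == pytest.approx(0.0)

    def test_two_by_two_hand_arithmetic(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        I = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert pp.srmr(S, I) == pytest.approx(np.sqrt(0.2**2 / 3))

    def test_rescaling_invariance(self, toy_moments):
        spec = pp.PathModelSpec(["y1", "y2"], ["x1", "x2"], {("x2", "y1")})
        fit_std = pp.fit_ml(toy_moments, spec)
        scaled = MomentSet(toy_moments.names, toy_moments.n, toy_moments.means,
                           toy_moments.sds * [2.0, 5.0, 0.3, 7.0],
                           toy_moments.corr)
        fit_scl = pp.fit_ml(scaled, spec)
        a = pp.srmr(fit_std.sample_cov, fit_std.implied_cov)
        b = pp.srmr(fit_scl.sample_cov, fit_scl.implied_cov)
        # agreement limited by the optimizer tolerance of the two fits
        assert a == pytest.approx(b, abs=1e-6)
        assert fit_std.F_ML == pytest.approx(fit_scl.F_ML, abs=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pp.srmr(np.eye(2), np.eye(3))


class TestSaturatedIdealValues:
    def test_all_indices_ideal(self, toy_moments):
        fit = pp.fit_ml(toy_moments, pp.PathModelSpec(["y1", "y2"], ["x1", "x2"]))
        rep = pp.fit_index_report(fit, toy_moments)
        assert rep.chi2 == pytest.approx(0.0, abs=1e-10)
        assert rep.cfi == 1.0
        assert rep.srmr == pytest.approx(0.0, abs=1e-10)
        assert rep.rmsea == 0.0


def _heavy_table(rng, C, n):
    Z = rng.multivariate_normal(np.zeros(C.shape[0]), C, size=n)
    W = rng.chisquare(5, size=(n, 1)) / 5
    return Z / np.sqrt(W)


class TestRobustScaling:
    C = np.array(
        [[1.0, 0.3, 0.0, 0.4, 0.1],
         [0.3, 1.0, 0.0, 0.1, 0.35],
         [0.0, 0.0, 1.0, 0.0, 0.0],
         [0.4, 0.1, 0.0, 1.0, 0.3],
         [0.1, 0.35, 0.0, 0.3, 1.0]]
    )
    spec = pp.PathModelSpec(["y1", "y2"], ["x1", "x2", "x3"],
                            {("x3", "y1"), ("x3", "y2")})

    def _tab(self, X):
        return simple_table(X, 3)

    def test_normal_data_factor_near_one(self):
        rng = np.random.default_rng(7)
        X = rng.multivariate_normal(np.zeros(5), self.C, size=2000)
        c, chi2_sc = pp.satorra_bentler_scaling(self._tab(X), self.spec)
        assert c == pytest.approx(1.0, abs=0.05)

    def test_heavy_tails_inflate_factor(self):
        rng = np.random.default_rng(8)
        c, _ = pp.satorra_bentler_scaling(
            self._tab(_heavy_table(rng, self.C, 2000)), self.spec)
        assert c > 1.0

    def test_scaled_chi_square_identity(self):
        rng = np.random.default_rng(9)
        X = rng.multivariate_normal(np.zeros(5), self.C, size=500)
        tab = self._tab(X)
        c, chi2_sc = pp.satorra_bentler_scaling(tab, self.spec)
        chi2, _ = pp.fit_ml(tab, self.spec).chi_square()
        assert chi2_sc * c == pytest.approx(chi2, rel=1e-10)

    def test_saturated_model_rejected(self):
        rng = np.random.default_rng(10)
        X = rng.multivariate_normal(np.zeros(5), self.C, size=200)
        with pytest.raises(ValueError, match="saturated"):
            pp.satorra_bentler_scaling(
                self._tab(X), pp.PathModelSpec(["y1", "y2"], ["x1", "x2", "x3"]))
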