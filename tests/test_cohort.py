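"""Scoring, missing-data policy, descriptives and internal consistency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pathprog as pp
from pathprog.cohort import (
    MissingnessWarning,
    PatientTable,
    VariableDef,
    daycase_roster,
)


def _scale(name):
    return next(v for v in daycase_roster() if v.name == name)


class TestScoreScale:
    @pytest.mark.parametrize(
        "scale,items,expected",
        [
            ("t0_stai_trait", [1] * 20, 20),      # scale floor
            ("t0_hads_a", [3] * 7, 21),           # scale ceiling
            ("t1_mfi", [5] * 20, 100),
        ],
    )
    def test_boundary_sums(self, scale, items, expected):
        assert pp.score_scale(items, _scale(scale)) == expected

    def test_plain_arithmetic_sum_on_toy_scale(self):
        toy = VariableDef("toy", "outcome", "T1", "continuous", (4, 16),
                          n_items=4, item_range=(1, 4))
        assert pp.score_scale([1, 2, 3, 4], toy) == 10

    def test_matrix_input_sums_rows(self):
        out = pp.score_scale(np.ones((5, 7)) * 2, _scale("t0_hads_a"))
        assert np.all(out == 14)

    @given(st.permutations(list(range(1, 8))))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_permutation_invariant(self, items):
        # item order never changes a sum score
        items = [min(i, 3) for i in items]
        ref = pp.score_scale(sorted(items), _scale("t0_hads_a"))
        assert pp.score_scale(items, _scale("t0_hads_a")) == ref

    def test_wrong_item_count_rejected(self):
        with pytest.raises(ValueError, match="items"):
            pp.score_scale([1] * 19, _scale("t0_stai_trait"))

    def test_out_of_range_item_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            pp.score_scale([0] + [1] * 19, _scale("t0_stai_trait"))


class TestMissingnessPolicy:
    def _toy(self):
        data = pd.DataFrame({
            "a": [1.0] * 10,
            "b": [1, 2, 3, 4, 5, 6, 7, 8, np.nan, np.nan],
        })
        roster = [VariableDef("a", "psych_predictor", "T0"),
                  VariableDef("b", "psych_predictor", "T0")]
        return PatientTable(roster, data)

    def test_no_missing_identity(self):
        t = self._toy().subset(["a"])
        out, dropped = pp.apply_missingness_policy(t, ["a"])
        assert out.n_enrolled == 10 and dropped == {"a": 0}

    def test_listwise_drop_counts(self):
        with pytest.warns(MissingnessWarning):
            out, dropped = pp.apply_missingness_policy(self._toy(), ["a", "b"])
        assert out.n_enrolled == 8
        assert dropped == {"a": 0, "b": 2}

    def test_idempotent(self):
        with pytest.warns(MissingnessWarning):
            once, _ = pp.apply_missingness_policy(self._toy(), ["a", "b"])
        twice, _ = pp.apply_missingness_policy(once, ["a", "b"])
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_follow_up_loss_emulation(self):
        # enrolled cohort with ~4% whole-row day-7 loss, as in the study
        table = pp.generate_cohort(pp.SyntheticConfig(seed=5))
        out, _ = pp.apply_missingness_policy(table, table.names)
        lost = table.n_enrolled - out.n_enrolled
        assert 398 * 0.005 < lost < 398 * 0.10

    def test_unknown_variable_rejected(self):
        with pytest.raises(KeyError):
            pp.apply_missingness_policy(self._toy(), ["nope"])


class TestDescribe:
    def test_binary_percentages_match_study_counts(self):
        # 174 female / 224 male -> 43.7% / 56.3%
        data = pd.DataFrame({"sex": [1.0] * 174 + [0.0] * 224})
        t = PatientTable([VariableDef("sex", "demographic", "T0", "binary",
                                      (0, 1))], data)
        rep = pp.describe(t)
        counts = rep.categorical["sex"]
        assert counts[1.0][0] == 174
        assert counts[1.0][1] == pytest.approx(43.7, abs=0.05)
        assert counts[0.0][1] == pytest.approx(56.3, abs=0.05)
        assert sum(pct for _, pct in counts.values()) == pytest.approx(100, abs=0.1)

    def test_constant_column_percentiles(self):
        t = PatientTable([VariableDef("c", "medical", "T0")],
                         pd.DataFrame({"c": [7.0] * 9}))
        assert pp.describe(t).percentiles["c"] == (7.0, 7.0, 7.0)

    def test_median_of_small_column(self):
        t = PatientTable([VariableDef("c", "medical", "T0")],
                         pd.DataFrame({"c": [1.0, 2, 3, 4, 5]}))
        assert pp.describe(t).percentiles["c"][1] == 3.0

    def test_empty_table_rejected(self):
        t = PatientTable([VariableDef("c", "medical", "T0")],
                         pd.DataFrame({"c": []}))
        with pytest.raises(ValueError):
            pp.describe(t)


class TestCronbachAlpha:
    def test_perfectly_correlated_items(self):
        x = np.arange(10.0)
        assert pp.cronbach_alpha(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_parallel_items_closed_form(self):
        # k equicorrelated items: alpha = k r / (1 + (k-1) r).  Construct
        # data whose *sample* covariance is exactly the equicorrelation
        # matrix, so the identity holds exactly.
        k, r, n = 4, 0.3, 50
        C = np.full((k, k), r)
        np.fill_diagonal(C, 1.0)
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((n, k))
        Z -= Z.mean(axis=0)
        white = np.linalg.cholesky(np.linalg.inv(np.cov(Z, rowvar=False)))
        X = Z @ white @ np.linalg.cholesky(C).T
        expected = k * r / (1 + (k - 1) * r)
        assert pp.cronbach_alpha(X) == pytest.approx(expected, abs=1e-10)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(1)
        alpha = pp.cronbach_alpha(rng.standard_normal((20000, 5)))
        assert abs(alpha) < 0.05

    def test_zero_total_variance_rejected(self):
        x = np.array([[1.0, -1.0]] * 5)
        with pytest.raises(ValueError, match="variance"):
            pp.cronbach_alpha(x)


def test_roster_json_round_trip():
    from pathprog.cohort import roster_from_json, roster_to_json

    roster = daycase_roster(extended=True)
    assert roster_from_json(roster_to_json(roster)) == roster


def test_roster_invariants():
    roster = daycase_roster(extended=True)
    assert len(roster) == 28
    for v in roster:
        if v.role == "outcome":
            assert v.timepoint == "T1"
        if v.kind == "binary":
            assert v.valid_range == (0, 1)


def test_table_range_validation():
    with pytest.raises(ValueError, match="valid range"):
        PatientTable(
            [VariableDef("t0_hads_a", "psych_predictor", "T0",
                         "continuous", (0, 21))],
            pd.DataFrame({"t0_hads_a": [22.0]}),
        )
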