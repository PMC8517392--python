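"""Two-group tests, correlation, regression and agreement statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pslwork import (
    CollinearityError,
    ValidationError,
    bland_altman,
    chi_square_2x2,
    mann_whitney,
    ols_standardized,
    pearson_r,
    stepwise_select,
    t_from_raw,
    t_from_summary,
)
from conftest import exact_moments


class TestPooledT:
    @pytest.mark.parametrize(
        "summary, expected_t",
        [
            ((50, 46.88, 10.60, 50, 50.20, 9.73), -1.632),  # age
            ((50, 118.84, 3.94, 50, 120.68, 6.00), -1.813),  # systolic BP
            ((50, 1899.84, 173.47, 50, 1712.80, 249.44), 4.353),  # work index
        ],
    )
    def test_published_group_summaries_reproduce(self, summary, expected_t):
        assert t_from_summary(*summary).statistic == pytest.approx(
            expected_t, abs=5e-4
        )

    def test_identical_groups(self):
        res = t_from_summary(30, 5.0, 1.0, 30, 5.0, 1.0)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_raw_equals_summary_on_exact_moments(self):
        rng = np.random.default_rng(0)
        x1 = exact_moments(rng.normal(size=50), 46.88, 10.60)
        x2 = exact_moments(rng.normal(size=50), 50.20, 9.73)
        raw = t_from_raw(x1, x2)
        summ = t_from_summary(50, 46.88, 10.60, 50, 50.20, 9.73)
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-9)
        assert raw.p_value == pytest.approx(summ.p_value, abs=1e-9)

    def test_antisymmetry_and_scipy_agreement(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(0, 1, 40), rng.normal(0.4, 1.2, 35)
        res = t_from_raw(x1, x2)
        swapped = t_from_raw(x2, x1)
        assert swapped.statistic == pytest.approx(-res.statistic, rel=1e-12)
        ref = sps.ttest_ind(x1, x2, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            t_from_summary(1, 0.0, 1.0, 10, 0.0, 1.0)
        with pytest.raises(ValidationError):
            t_from_summary(10, 0.0, 0.0, 10, 0.0, 1.0)


def brute_force_u(x1, x2):
    """Exhaustive pair-count U: wins count 1, ties count 1/2."""
    u = 0.0
    for a in x1:
        for b in x2:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        # all 9 pairs favor group 2
        assert brute_force_u([1, 2, 3], [4, 5, 6]) == 0.0
        assert res.statistic < 0

    def test_identical_multisets_give_zero_z(self):
        x = [1.0, 2.0, 2.0, 3.0]
        res = mann_whitney(x, list(x))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        x1=st.lists(st.integers(0, 6), min_size=1, max_size=8),
        x2=st.lists(st.integers(0, 6), min_size=1, max_size=8),
    )
    def test_u_matches_exhaustive_pair_count(self, x1, x2):
        """Midrank U equals brute-force enumeration, ties included."""
        pooled = np.concatenate([x1, x2]).astype(float)
        ranks = sps.rankdata(pooled)
        u1 = ranks[: len(x1)].sum() - len(x1) * (len(x1) + 1) / 2.0
        assert u1 == brute_force_u(x1, x2)
        mann_whitney(x1, x2)  # never raises on valid input

    def test_p_value_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(2)
        x1 = np.round(rng.normal(0, 1, 30), 1)  # rounding creates ties
        x2 = np.round(rng.normal(0.5, 1, 25), 1)
        res = mann_whitney(x1, x2)
        ref = sps.mannwhitneyu(
            x1, x2, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestChiSquare:
    @pytest.mark.parametrize(
        "table, expected",
        [((29, 21, 26, 24), 0.364), ((12, 38, 14, 36), 0.208)],
    )
    def test_published_counts_reproduce(self, table, expected):
        assert chi_square_2x2(*table).statistic == pytest.approx(expected, abs=5e-4)

    def test_proportional_table_gives_zero(self):
        assert chi_square_2x2(10, 10, 20, 20).statistic == 0.0

    def test_transposition_invariance(self):
        a, b, c, d = 29, 21, 26, 24
        original = chi_square_2x2(a, b, c, d).statistic
        assert chi_square_2x2(a, c, b, d).statistic == pytest.approx(
            original, rel=1e-12
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_2x2(0, 0, 5, 5)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestOLS:
    def test_exact_fit(self):
        x = np.linspace(-2, 5, 40)
        res = ols_standardized(x.copy(), x, names=["x"])
        assert res.beta["x"] == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_null_model_r_squared_small(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=1000)
        X = rng.normal(size=(1000, 3))
        res = ols_standardized(y, X)
        assert res.r_squared < 0.02
        assert res.adj_r_squared <= res.r_squared

    def test_univariable_standardized_beta_equals_pearson_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=120)
        y = 0.6 * x + rng.normal(size=120)
        res = ols_standardized(y, x, names=["x"])
        r, _ = pearson_r(x, y)
        assert res.beta["x"] == pytest.approx(r, abs=1e-9)

    def test_collinearity_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(CollinearityError):
            ols_standardized(rng.normal(size=50), X)


class TestStepwise:
    def test_orthogonal_design_selects_true_predictor_only(self):
        rng = np.random.default_rng(6)
        n = 500
        q, _ = np.linalg.qr(rng.normal(size=(n, 4)))  # orthogonal columns
        X = q * np.sqrt(n)
        y = 0.5 * X[:, 1] + rng.normal(size=n)
        res = stepwise_select(y, X, names=["a", "b", "c", "d"])
        assert res.predictors == ("b",)
        assert res.beta["b"] < 0.6

    def test_all_null_with_tiny_entry_threshold_gives_empty_model(self):
        rng = np.random.default_rng(7)
        res = stepwise_select(
            rng.normal(size=200), rng.normal(size=(200, 3)),
            p_enter=1e-9, p_remove=1e-9,
        )
        assert res.empty
        assert res.r_squared == 0.0

    def test_permissive_thresholds_select_everything(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 3))
        y = rng.normal(size=100)
        res = stepwise_select(y, X, names=["a", "b", "c"], p_enter=1.0, p_remove=1.0)
        assert set(res.predictors) == {"a", "b", "c"}

    def test_entry_threshold_order_validated(self):
        with pytest.raises(ValidationError):
            stepwise_select([1.0, 2.0, 3.0], [[1.0], [2.0], [3.0]],
                            p_enter=0.5, p_remove=0.1)


class TestBlandAltman:
    def test_identical_measurements(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    def test_constant_shift(self):
        m1 = np.array([1.0, 2.0, 3.0])
        res = bland_altman(m1, m1 + 5.0)
        assert res.bias == pytest.approx(5.0)
        assert res.loa_low == pytest.approx(5.0)
        assert res.loa_high == pytest.approx(5.0)

    def test_bias_is_difference_of_paired_means(self):
        rng = np.random.default_rng(9)
        m1 = exact_moments(rng.normal(size=20), 36.65, 15.28)
        m2 = exact_moments(rng.normal(size=20), 39.90, 16.37)
        res = bland_altman(m1, m2)
        assert res.bias == pytest.approx(39.90 - 36.65, abs=1e-9)
        assert res.loa_low <= res.bias <= res.loa_high
        # symmetric limits around the bias
        assert res.loa_high - res.bias == pytest.approx(res.bias - res.loa_low)

    def test_swap_negates_bias_and_mirrors_limits(self):
        rng = np.random.default_rng(10)
        m1, m2 = rng.normal(size=15), rng.normal(size=15)
        r12, r21 = bland_altman(m1, m2), bland_altman(m2, m1)
        assert r21.bias == pytest.approx(-r12.bias)
        assert r21.loa_low == pytest.approx(-r12.loa_high)
        assert r21.loa_high == pytest.approx(-r12.loa_low)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0, 2.0], [1.0])
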