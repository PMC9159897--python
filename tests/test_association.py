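"""Association-suite tests: published statistics, oracles and invariants."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rehabspc import (
    ContingencyTable,
    DegenerateTableError,
    analyze_2x2,
    cramers_v,
    fisher_exact_2x2,
    linear_by_linear,
    odds_ratio_2x2,
    ols_regression,
    one_way_anova,
    pearson_chi_square,
    pearson_correlation,
    reference_tables,
)
from rehabspc.association import cramers_v_band, eta_squared_band

from conftest import random_2x2


def chi2_closed_form(t):
    """Independent closed form for 2x2: N(ad-bc)^2 / product of margins."""
    (a, b), (c, d) = np.asarray(t)
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def fisher_enumeration(t):
    """Two-sided Fisher p by exhausting all tables with the observed margins."""
    (a, b), (c, d) = np.asarray(t)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestPublishedStatistics:
    """The trial's printed contingency statistics, from transcribed counts."""

    def test_reference_tables_counts(self, ref_tables):
        assert ref_tables["treatment_outcome"].counts.tolist() == [[27, 5], [15, 12]]
        assert ref_tables["treatment_outcome"].n == 59
        assert ref_tables["stroke_treatment_outcome"].counts.tolist() == [[22, 4], [9, 11]]
        assert ref_tables["stroke_treatment_outcome"].n == 46
        assert ref_tables["highCR_treatment_outcome"].counts.tolist() == [[19, 2], [13, 8]]
        assert ref_tables["highCR_treatment_outcome"].n == 42

    @pytest.mark.parametrize(
        "name, chi2, fisher_p, v, orr",
        [
            ("treatment_outcome", 5.930, 0.021, 0.317, 0.231),
            ("stroke_treatment_outcome", 8.073, 0.010, 0.419, 0.149),
            ("highCR_treatment_outcome", 4.725, None, 0.335, None),
        ],
    )
    def test_full_bundle(self, ref_tables, name, chi2, fisher_p, v, orr):
        res = analyze_2x2(ref_tables[name])
        assert res.chi_square == pytest.approx(chi2, abs=5e-4)
        assert res.cramers_v == pytest.approx(v, abs=5e-4)
        if fisher_p is not None:
            assert res.fisher_p == pytest.approx(fisher_p, abs=5e-4)
        if orr is not None:
            assert res.odds_ratio.odds_ratio == pytest.approx(orr, abs=5e-4)

    def test_headline_odds_ratio_interval_and_reciprocal(self, ref_tables):
        res = odds_ratio_2x2(ref_tables["treatment_outcome"])
        assert res.ci_low == pytest.approx(0.068, abs=5e-4)
        assert res.ci_high == pytest.approx(0.784, abs=5e-4)
        assert res.reciprocal == pytest.approx(4.32, abs=5e-3)
        assert res.ci_low <= res.odds_ratio <= res.ci_high


class TestChiSquare:
    def test_independence_gives_zero(self):
        chi2, df, p = pearson_chi_square([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi_square([[5, 0], [7, 0]])

    def test_matches_closed_form_on_random_tables(self, rng):
        for _ in range(300):
            t = random_2x2(rng)
            chi2, _, _ = pearson_chi_square(t)
            assert chi2 == pytest.approx(chi2_closed_form(t), abs=1e-9)

    def test_invariant_under_permutation_and_transpose(self, rng):
        t = ContingencyTable(np.array([[27, 5], [15, 12]]))
        base = analyze_2x2(t)
        for variant in (t.transpose(), ContingencyTable(t.counts[::-1].copy())):
            other = analyze_2x2(variant)
            assert other.chi_square == pytest.approx(base.chi_square, abs=1e-12)
            assert other.cramers_v == pytest.approx(base.cramers_v, abs=1e-12)
            assert other.fisher_p == pytest.approx(base.fisher_p, abs=1e-12)


class TestFisher:
    def test_two_table_enumeration_case(self):
        # margins (1,1)x(1,1): two tables, each probability 0.5
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            t = random_2x2(rng, n_max=100)
            p = fisher_exact_2x2(t)
            assert 0 < p <= 1
            assert p == pytest.approx(fisher_enumeration(t), abs=1e-9)


class TestCramersV:
    def test_null_statistic_gives_zero(self):
        assert cramers_v(0.0, 50, 2, 2) == 0.0

    @pytest.mark.parametrize("chi2, n, expected", [(5.930, 59, 0.317), (8.073, 46, 0.419)])
    def test_published_values(self, chi2, n, expected):
        assert cramers_v(chi2, n, 2, 2) == pytest.approx(expected, abs=5e-4)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(200):
            t = random_2x2(rng)
            chi2, _, _ = pearson_chi_square(t)
            v = cramers_v(chi2, t.sum(), 2, 2)
            assert 0.0 <= v <= 1.0

    def test_bands(self):
        assert cramers_v_band(0.2) == "weak"
        assert cramers_v_band(0.317) == "moderate"
        assert cramers_v_band(0.6) == "strong"


class TestOddsRatio:
    def test_equal_odds_is_one(self):
        assert odds_ratio_2x2([[8, 8], [3, 3]]).odds_ratio == pytest.approx(1.0)

    def test_column_swap_inverts(self, rng):
        for _ in range(100):
            t = random_2x2(rng)
            if np.any(t == 0):
                continue
            a = odds_ratio_2x2(t).odds_ratio
            b = odds_ratio_2x2(t[:, ::-1]).odds_ratio
            assert a * b == pytest.approx(1.0, abs=1e-12)

    def test_zero_cell_flags_ci_unavailable(self):
        res = odds_ratio_2x2([[5, 0], [3, 2]])
        assert not res.ci_available and res.ci_low is None

    def test_zero_cell_with_continuity_correction(self):
        res = odds_ratio_2x2([[5, 0], [3, 2]], continuity_correction=True)
        assert res.ci_available and res.continuity_corrected
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_ci_brackets_estimate_for_positive_tables(self, rng):
        for _ in range(100):
            t = random_2x2(rng)
            if np.any(t == 0):
                continue
            res = odds_ratio_2x2(t)
            assert res.ci_low <= res.odds_ratio <= res.ci_high


class TestAnova:
    def test_identical_groups_define_f_zero(self):
        res = one_way_anova([[3, 3, 3], [3, 3, 3]])
        assert (res.f_statistic, res.p_value, res.eta_squared) == (0.0, 1.0, 0.0)

    def test_hand_computed_two_groups(self):
        res = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert res.f_statistic == pytest.approx(13.5)
        assert res.eta_squared == pytest.approx(13.5 / 17.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_eta_squared_identity(self, rng):
        for _ in range(50):
            groups = [rng.normal(size=rng.integers(3, 9)) for _ in range(rng.integers(2, 5))]
            res = one_way_anova(groups)
            implied = res.f_statistic * res.df_between / (
                res.f_statistic * res.df_between + res.df_within
            )
            assert res.eta_squared == pytest.approx(implied, abs=1e-12)

    def test_f_equals_t_squared_for_two_groups(self, rng):
        for _ in range(50):
            a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=6)
            res = one_way_anova([a, b])
            t, p = stats.ttest_ind(a, b, equal_var=True)
            assert res.f_statistic == pytest.approx(t**2, abs=1e-9)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(size=7), rng.normal(size=5), rng.normal(size=9)]
        res = one_way_anova(groups)
        f, p = stats.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(f, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_band_thresholds(self):
        assert eta_squared_band(0.14) == "large"
        assert eta_squared_band(0.07) == "medium"
        assert eta_squared_band(0.02) == "small"


class TestPearsonCorrelation:
    def test_perfect_lines(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        r, p = pearson_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestOlsRegression:
    def test_exact_line_has_unit_r2(self):
        x = np.arange(10.0)
        res = ols_regression(x[:, None], 2 * x + 1)
        assert res.r_squared == pytest.approx(1.0)
        assert res.params == pytest.approx([1.0, 2.0], abs=1e-10)

    def test_orthogonal_response_has_zero_r2(self):
        x = np.array([-1.5, -0.5, 0.5, 1.5])
        y = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to x and centred
        res = ols_regression(x[:, None], y)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(30, 3))
        y = (rng.random(30) < 0.5).astype(float)
        res = ols_regression(X, y)
        Xc = np.column_stack([np.ones(30), X])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        assert res.params == pytest.approx(beta, abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.arange(8.0), 2 * np.arange(8.0)])
        with pytest.raises(ValueError, match="rank"):
            ols_regression(X, np.ones(8))


class TestLinearByLinear:
    def test_flat_table_gives_zero(self):
        stat, p = linear_by_linear([[5, 5], [5, 5]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_correlation(self):
        stat, _ = linear_by_linear([[10, 0], [0, 10]])
        assert stat == pytest.approx(19.0)

    def test_matches_expansion_oracle(self, rng):
        for _ in range(100):
            t = random_2x2(rng)
            stat, _ = linear_by_linear(t)
            xs, ys = [], []
            for (i, j), count in np.ndenumerate(t):
                xs += [i + 1] * count
                ys += [j + 1] * count
            if len(set(xs)) < 2 or len(set(ys)) < 2:
                continue
            r = stats.pearsonr(xs, ys).statistic
            assert stat == pytest.approx((t.sum() - 1) * r**2, abs=1e-9)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            linear_by_linear([[5, 5], [5, 5]], row_scores=[1, 1])
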