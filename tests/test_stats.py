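"""Chi-square tests, ANOVAs, Spearman correlation and power computations."""

import numpy as np
import pytest
import scipy.stats

from gazehmm.stats import (
    ContingencyTable,
    PowerSpec,
    chisq_gof,
    chisq_independence,
    one_way_anova,
    two_way_anova,
    spearman,
    anova_power,
    anova_sample_size,
    inflate_sample_size,
)


class TestChisqGof:
    def test_published_female_face_counts(self):
        chi2, df, p = chisq_gof([199, 131])
        assert chi2 == pytest.approx(14.01, abs=0.005)
        assert df == 1 and p < 0.001

    def test_published_male_face_counts(self):
        chi2, _, p = chisq_gof([237, 93])
        assert chi2 == pytest.approx(62.84, abs=0.005)
        assert p < 0.001

    def test_child_face_counts_recompute_differently_than_printed(self):
        # published statistic 85.53 is inconsistent with its own counts
        chi2, _, _ = chisq_gof([248, 81])
        assert chi2 == pytest.approx(84.77, abs=0.005)
        assert abs(chi2 - 85.53) > 0.5

    def test_balanced_counts_give_zero(self):
        chi2, df, p = chisq_gof([165, 165])
        assert chi2 == 0.0 and p == 1.0

    def test_zero_expected_cell_errors(self):
        with pytest.raises(ValueError):
            chisq_gof([10, 10], [1.0, 0.0])

    def test_type_i_error_calibrated_under_null(self):
        # multinomial null, alpha = 0.05: rejection rate in binomial 99% CI
        rng = np.random.default_rng(2024)
        n_rep, rejections = 1000, 0
        for _ in range(n_rep):
            counts = rng.multinomial(300, [0.25] * 4)
            _, _, p = chisq_gof(counts)
            rejections += p < 0.05
        lo, hi = scipy.stats.binom.interval(0.99, n_rep, 0.05)
        assert lo <= rejections <= hi


class TestChisqIndependence:
    def test_outer_product_table_is_independent(self):
        row = np.array([0.3, 0.7])
        col = np.array([0.2, 0.5, 0.3])
        table = np.round(np.outer(row, col) * 1000)
        chi2, _, p = chisq_independence(table)
        assert chi2 == pytest.approx(0.0, abs=0.2)

    def test_hand_computed_diagonal_table(self):
        chi2, df, _ = chisq_independence(np.array([[10, 0], [0, 10]]))
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_row_permutation_invariance(self):
        t1 = np.array([[12, 5, 9], [3, 14, 6]])
        c1, _, _ = chisq_independence(t1)
        c2, _, _ = chisq_independence(t1[::-1])
        assert c1 == pytest.approx(c2)

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError):
            chisq_independence(np.array([[0, 0], [3, 4]]))

    def test_contingency_table_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable(["a"], ["b"], np.array([[-1]]))


class TestOneWayAnova:
    def test_all_constant_groups_undefined(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])

    def test_two_groups_equal_pooled_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 15)
        F, _, _, p_f = one_way_anova([a, b])
        t, p_t = scipy.stats.ttest_ind(a, b)
        assert F == pytest.approx(t ** 2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_null_f_near_one_on_average(self):
        rng = np.random.default_rng(7)
        fs = []
        for _ in range(1000):
            groups = [rng.normal(0, 1, 10) for _ in range(3)]
            F, _, _, _ = one_way_anova(groups)
            fs.append(F)
        # E[F] = df2 / (df2 - 2) = 27/25 = 1.08 under the null
        assert np.mean(fs) == pytest.approx(27 / 25, abs=0.1)

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(99)
        n_rep, rejections = 1000, 0
        for _ in range(n_rep):
            groups = [rng.normal(0, 1, 8) for _ in range(4)]
            _, _, _, p = one_way_anova(groups)
            rejections += p < 0.05
        lo, hi = scipy.stats.binom.interval(0.99, n_rep, 0.05)
        assert lo <= rejections <= hi


class TestTwoWayAnova:
    def test_balanced_additive_design_no_interaction(self):
        rng = np.random.default_rng(11)
        a = np.repeat(["a1", "a2"], 60)
        b = np.tile(np.repeat(["b1", "b2", "b3"], 20), 2)
        effects_a = {"a1": 0.0, "a2": 1.0}
        effects_b = {"b1": 0.0, "b2": 0.5, "b3": -0.5}
        y = np.array([effects_a[x] + effects_b[z] for x, z in zip(a, b)])
        y = y + rng.normal(0, 1, len(y))
        tab = two_way_anova(y, a, b)
        assert tab.loc["A", "p"] < 0.01  # real main effect
        assert tab.loc["A:B", "p"] > 0.01  # no interaction built in

    def test_single_level_factor_errors(self):
        with pytest.raises(ValueError):
            two_way_anova([1.0, 2.0], ["a", "a"], ["b", "c"])

    def test_empty_cell_named_in_error(self):
        vals = [1.0, 2.0, 3.0]
        with pytest.raises(ValueError, match="empty design cell"):
            two_way_anova(vals, ["a1", "a1", "a2"], ["b1", "b2", "b1"])

    def test_balanced_type2_equals_type1(self):
        rng = np.random.default_rng(3)
        a = np.repeat(["a1", "a2"], 30)
        b = np.tile(np.repeat(["b1", "b2"], 15), 2)
        y = rng.normal(0, 1, 60)
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        import pandas as pd
        df = pd.DataFrame({"value": y, "a": a, "b": b})
        t1 = anova_lm(smf.ols("value ~ C(a) * C(b)", df).fit(), typ=1)
        t2 = two_way_anova(y, a, b)
        assert t2.loc["A", "sum_sq"] == pytest.approx(t1.loc["C(a)", "sum_sq"])
        assert t2.loc["A:B", "sum_sq"] == pytest.approx(t1.loc["C(a):C(b)", "sum_sq"])


class TestSpearman:
    def test_perfect_monotone_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, -np.exp(x))[0] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # d^2 = (1,1,1,1,0): rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rho0, _ = spearman(x, y)
        rho1, _ = spearman(np.exp(x), y)
        rho2, _ = spearman(x, y ** 3)
        assert rho1 == pytest.approx(rho0)
        assert rho2 == pytest.approx(rho0)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPower:
    def test_power_monotone_in_n(self):
        powers = [anova_power(N, 0.25, 8, 0.05) for N in range(20, 500, 40)]
        assert all(b >= a for a, b in zip(powers, powers[1:]))

    def test_minimum_n_brackets_target_power(self):
        spec = PowerSpec(effect_size_f=0.25, n_groups=8, alpha=0.05, target_power=0.90)
        N = anova_sample_size(spec)
        assert anova_power(N, 0.25, 8, 0.05) >= 0.90
        assert anova_power(N - 1, 0.25, 8, 0.05) < 0.90

    def test_inflation_arithmetic(self):
        assert inflate_sample_size(338, 0.15, 0.50) == 796
        assert inflate_sample_size(100, 0.0, 1.0) == 100
        assert inflate_sample_size(100, 0.5, 0.5) == 400

    def test_inflation_validates_rates(self):
        with pytest.raises(ValueError):
            inflate_sample_size(100, 1.0, 0.5)
        with pytest.raises(ValueError):
            inflate_sample_size(100, 0.1, 0.0)

    def test_power_spec_validation(self):
        with pytest.raises(ValueError):
            PowerSpec(effect_size_f=0.25, n_groups=1)
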