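import math

import numpy as np
import pytest
from scipy import stats as sps

import lesionquant as lq
from lesionquant.stats import posthoc_pairwise
from oracles import anova_f_by_hand, chi2_permutation_p, fisher_two_sided_exact


class TestIncidence:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(4, 7, 57.1), (1, 8, 12.5), (0, 5, 0.0), (9, 9, 100.0), (2, 7, 28.6), (3, 7, 42.9)],
    )
    def test_printed_style_percentages(self, k, n, expected):
        assert lq.incidence_percent(k, n) == expected

    def test_round_half_up(self):
        # 1/16 = 6.25% -> 6.3 under half-up (banker's rounding would give 6.2)
        assert lq.incidence_percent(1, 16) == 6.3

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            lq.incidence_percent(0, 0)


class TestSummarizeArm:
    def test_all_zero_values(self):
        s = lq.summarize_arm("a", [0, 0, 0])
        assert (s.k_affected, s.mean, s.sd) == (0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        s = lq.summarize_arm("a", [1, 2, 3])
        assert s.mean == 2.0
        assert s.sd == pytest.approx(1.0)
        assert s.n == 3
        assert s.k_affected == 3

    def test_custom_affected_rule(self):
        s = lq.summarize_arm("a", [0.1, 0.5, 0.9], affected_rule=lambda v: v > 0.4)
        assert s.k_affected == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lq.summarize_arm("a", [])


class TestPooledT:
    def test_reported_group_summaries(self):
        """Pooled t on the 12.0 ± 10.07 (n=9) vs 2.86 ± 5.43 (n=7) lesion
        counts reproduces the reported p = 0.0487."""
        r = lq.pooled_t_test(12.0, 10.07, 9, 2.86, 5.43, 7)
        assert r.df == 14
        assert r.statistic == pytest.approx(2.159, abs=0.001)
        assert r.p_value == pytest.approx(0.0487, abs=0.0005)

    def test_identical_summaries_null(self):
        r = lq.pooled_t_test(5.0, 2.0, 6, 5.0, 2.0, 6)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_t_distribution_quantile_cross_check(self):
        # t = 2.1448 is the 97.5% quantile at df 14
        r = lq.pooled_t_test(2.1448 * math.sqrt(2 / 8), 1.0, 8, 0.0, 1.0, 8)
        assert r.p_value == pytest.approx(0.0500, abs=0.0002)

    def test_degenerate_zero_variance_flagged(self):
        r = lq.pooled_t_test(1.0, 0.0, 3, 1.0, 0.0, 3)
        assert r.p_value == 1.0 and "degenerate" in r.note
        r2 = lq.pooled_t_test(2.0, 0.0, 3, 1.0, 0.0, 3)
        assert r2.p_value == 0.0

    def test_matches_scipy_from_stats(self, rng):
        for _ in range(10):
            m1, m2 = rng.normal(size=2)
            s1, s2 = rng.uniform(0.5, 3, size=2)
            n1, n2 = rng.integers(3, 20, size=2)
            ours = lq.pooled_t_test(m1, s1, int(n1), m2, s2, int(n2))
            ref = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_welch_variant(self):
        r = lq.welch_t_test(12.0, 10.07, 9, 2.86, 5.43, 7)
        ref = sps.ttest_ind_from_stats(12.0, 10.07, 9, 2.86, 5.43, 7, equal_var=False)
        assert r.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestChiSquare:
    def test_proportional_table_is_null(self):
        r = lq.chi_square_2x2(2, 4, 3, 6)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_closed_form_example(self):
        r = lq.chi_square_2x2(9, 0, 4, 3)
        assert r.statistic == pytest.approx(4.747, abs=0.001)
        assert r.p_value == pytest.approx(0.0294, abs=0.0005)

    def test_invariant_under_row_and_column_swap(self):
        a = lq.chi_square_2x2(9, 2, 4, 7)
        assert lq.chi_square_2x2(4, 7, 9, 2).statistic == pytest.approx(a.statistic)
        assert lq.chi_square_2x2(2, 9, 7, 4).statistic == pytest.approx(a.statistic)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            lq.chi_square_2x2(0, 0, 3, 4)

    @pytest.mark.parametrize("table", [(120, 80, 100, 100), (60, 40, 45, 55)])
    def test_matches_permutation_null(self, table):
        """Monte-Carlo permutation null (margins fixed, mid-P for ties)
        within 3 SE, on tables large enough for the asymptotics to hold."""
        r = lq.chi_square_2x2(*table)
        n_perm = 100_000
        p_perm = chi2_permutation_p(*table, n_perm=n_perm, seed=7)
        se = math.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_perm - r.p_value) <= 3 * se

    def test_yates_correction_shrinks_statistic(self):
        assert (
            lq.chi_square_2x2(9, 0, 4, 3, yates=True).statistic
            < lq.chi_square_2x2(9, 0, 4, 3).statistic
        )


class TestFisher:
    def test_one_sided_tail_of_incidence_table(self):
        # P(X = 9) with 13 affected of 16, group size 9: C(13,9)/C(16,9)
        from math import comb

        tail = comb(13, 9) / comb(16, 9)
        assert tail == pytest.approx(0.0625)
        r = lq.fisher_exact_2x2(9, 0, 4, 3)
        assert r.p_value >= tail  # two-sided includes that tail

    def test_proportional_table_p_one(self):
        assert lq.fisher_exact_2x2(2, 4, 3, 6).p_value == pytest.approx(1.0)

    def test_transposition_invariance(self):
        assert lq.fisher_exact_2x2(9, 2, 4, 7).p_value == pytest.approx(
            lq.fisher_exact_2x2(9, 4, 2, 7).p_value
        )

    def test_matches_enumeration_on_small_tables(self):
        """Exhaustive hypergeometric enumeration oracle, tables with N <= 12."""
        for n in range(2, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                            continue
                        p = lq.fisher_exact_2x2(a, b, c, d).p_value
                        ref = float(fisher_two_sided_exact(a, b, c, d))
                        assert p == pytest.approx(ref, abs=1e-9), (a, b, c, d)


class TestAnova:
    def test_equal_means_nonzero_spread_gives_f_zero(self):
        r = lq.one_way_anova([[1, 3], [1, 3], [3, 1]])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_identical_constants_flagged(self):
        r = lq.one_way_anova([[2, 2], [2, 2]])
        assert math.isnan(r.statistic) and "degenerate" in r.note

    def test_two_groups_equals_t_squared(self, rng):
        for _ in range(10):
            a = rng.normal(size=8).tolist()
            b = rng.normal(1.0, 1.5, size=6).tolist()
            f = lq.one_way_anova([a, b])
            t = lq.pooled_t_test(
                float(np.mean(a)), float(np.std(a, ddof=1)), 8,
                float(np.mean(b)), float(np.std(b, ddof=1)), 6,
            )
            assert f.statistic == pytest.approx(t.statistic**2, rel=1e-9)
            assert abs(f.p_value - t.p_value) < 1e-9

    def test_three_group_toy_against_hand_sums(self):
        groups = [[1, 2], [2, 3], [3, 4]]
        r = lq.one_way_anova(groups)
        assert r.statistic == pytest.approx(anova_f_by_hand(groups))
        assert r.statistic == pytest.approx(4.0)
        assert r.df == (2, 3)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            lq.one_way_anova([[1], [2, 3]])

    def test_posthoc_bonferroni(self):
        groups = [[1.0, 2.0, 1.5], [2.0, 3.0, 2.5], [5.0, 6.0, 5.5]]
        res = posthoc_pairwise(groups, ["a", "b", "c"])
        assert len(res) == 3
        raw = lq.pooled_t_test(1.5, 0.5, 3, 2.5, 0.5, 3)
        ab = next(r for x, y, r in res if (x, y) == ("a", "b"))
        assert ab.p_value == pytest.approx(min(3 * raw.p_value, 1.0))
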