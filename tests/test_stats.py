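from itertools import combinations

import numpy as np
import pytest

from eegsmallworld.stats import (StatsError, independent_t_test,
                                 mann_whitney_u, mwu_p_asymptotic,
                                 pearson_correlation, shapiro_wilk,
                                 sweep_tests, t_from_summary)


class TestMannWhitney:
    def test_identical_groups_symmetric(self):
        res = mann_whitney_u(list(range(1, 15)), list(range(1, 15)))
        assert res.statistic == 98.0  # n1*n2/2
        assert res.p_two_sided == pytest.approx(1.0)

    def test_exact_p_by_enumeration(self):
        # all 20 assignments of {1..6} into two groups of 3: only one
        # split is as extreme in each direction -> two-sided p = 0.1
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], method="exact")
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(0.1)
        # independent brute-force enumeration
        pooled = [1, 2, 3, 4, 5, 6]
        observed_u = 0.0
        count_extreme = 0
        for comb in combinations(range(6), 3):
            a = [pooled[i] for i in comb]
            b = [pooled[i] for i in range(6) if i not in comb]
            u = sum(1 for x in a for y in b if x > y)
            u = min(u, 9 - u)
            if u <= observed_u:
                count_extreme += 1
        assert count_extreme / 20 == pytest.approx(res.p_two_sided)

    def test_companion_w_identity(self, rng):
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(5, 15)))
            b = rng.normal(size=int(rng.integers(5, 15)))
            res = mann_whitney_u(a, b)
            # W is the rank-sum of the group attaining the min U
            n_w = res.n1 if res.companion - res.statistic == res.n1 * (res.n1 + 1) / 2 else res.n2
            assert res.companion == pytest.approx(
                res.statistic + n_w * (n_w + 1) / 2)

    def test_exact_and_asymptotic_agree_at_study_size(self):
        # at n1 = n2 = 14 without ties the normal approximation tracks
        # the exact distribution to ~0.001 in the significant tail and
        # a few hundredths elsewhere
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.normal(size=14)
            b = rng.normal(0.5, size=14)
            p_asym = mann_whitney_u(a, b).p_two_sided
            p_exact = mann_whitney_u(a, b, method="exact").p_two_sided
            assert abs(p_asym - p_exact) < 0.03
            if p_exact < 0.02:
                assert abs(p_asym - p_exact) < 0.002

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney_u([], [1.0])

    def test_tie_correction_reduces_variance(self):
        # heavy ties shrink the null SD, making |z| larger
        a = [1, 1, 1, 2, 2, 3, 3]
        b = [2, 2, 3, 3, 3, 4, 4]
        res = mann_whitney_u(a, b)
        assert 0 < res.p_two_sided < 1


class TestTTests:
    def test_identical_groups(self):
        res = independent_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_summary_form_matches_raw(self, rng):
        a = rng.normal(10, 2, size=14)
        b = rng.normal(12, 3, size=14)
        raw = independent_t_test(a, b)
        summ = t_from_summary(a.mean(), a.std(ddof=1), 14, b.mean(), b.std(ddof=1), 14)
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-10)
        assert raw.p_two_sided == pytest.approx(summ.p_two_sided, rel=1e-10)

    def test_group_swap_negates_t(self, rng):
        a, b = rng.normal(size=10), rng.normal(1, 1, size=12)
        r1 = independent_t_test(a, b)
        r2 = independent_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsError):
            t_from_summary(1.0, 0.0, 10, 2.0, 1.0, 10)
        with pytest.raises(StatsError):
            independent_t_test([1.0], [2.0, 3.0])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_reversal_negates_r(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        r1 = pearson_correlation(x, y)
        r2 = pearson_correlation(x, -y)
        assert r1.r == pytest.approx(-r2.r)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)

    def test_null_rejection_rate_matches_critical_value(self):
        # |r| > 0.374 is the two-sided 5% cutoff at n = 28
        rng = np.random.default_rng(9)
        rs = np.array([pearson_correlation(rng.normal(size=28),
                                           rng.normal(size=28)).r
                       for _ in range(500)])
        assert abs(rs.mean()) < 0.03
        rate = np.mean(np.abs(rs) > 0.374)
        assert 0.02 <= rate <= 0.09

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestShapiroWilk:
    def test_type_i_error_rate(self):
        rng = np.random.default_rng(10)
        rejections = sum(shapiro_wilk(rng.normal(size=14)).p_two_sided < 0.05
                         for _ in range(500))
        assert 0.02 <= rejections / 500 <= 0.09

    def test_detects_lognormal_skew(self):
        rng = np.random.default_rng(11)
        detected = sum(shapiro_wilk(np.exp(rng.normal(size=50))).p_two_sided < 0.05
                       for _ in range(50))
        assert detected >= 45  # >= 90%

    def test_constant_sample_rejected(self):
        with pytest.raises(StatsError):
            shapiro_wilk([2.0] * 10)


class TestSweepTests:
    @staticmethod
    def _grids(rng, grid, shift=0.0):
        return {
            "C": {t: rng.normal(size=14) for t in grid},
            "L": {t: rng.normal(shift, 1, size=14) for t in grid},
        }

    def test_result_count(self, rng):
        grid = [round(t, 3) for t in np.arange(0.155, 0.4455, 0.005)]
        a = self._grids(rng, grid)
        b = self._grids(rng, grid)
        results, argmin_p = sweep_tests(a, b)
        assert len(results) == 118
        assert set(argmin_p) == {"C", "L"}

    def test_grid_mismatch_rejected(self, rng):
        a = self._grids(rng, [0.1, 0.2])
        b = self._grids(rng, [0.1, 0.3])
        with pytest.raises(StatsError):
            sweep_tests(a, b)

    def test_type_i_error_rate_per_grid_point(self):
        rng = np.random.default_rng(12)
        false_pos = 0
        n_reps = 200
        for _ in range(n_reps):
            a = {"L": {0.2: rng.normal(size=14)}}
            b = {"L": {0.2: rng.normal(size=14)}}
            results, _ = sweep_tests(a, b)
            false_pos += results[0].p_two_sided < 0.05
        assert 0.015 <= false_pos / n_reps <= 0.10

    def test_power_against_shifted_alternative(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(20):
            a = self._grids(rng, [0.2, 0.3], shift=1.5)
            b = self._grids(rng, [0.2, 0.3], shift=0.0)
            results, argmin_p = sweep_tests(a, b)
            l_ps = [r.p_two_sided for r in results if r.metric == "L"]
            hits += min(l_ps) < 0.05
        assert hits >= 16  # >= 80% of 20 seeded replications
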