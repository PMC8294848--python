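"""Exact counts, rank formulas, Cover's function."""

import itertools
import math

import numpy as np
import pytest

from gridplace.codebooks import (
    make_grid_codebook,
    make_grid_codebook_2d,
    make_modular_one_hot,
)
from gridplace.combinatorics import (
    asymptotic_two_module,
    capacity_dd,
    count_two_module,
    cover_count,
    log_asymptotic_two_module,
    poly_bernoulli_neg,
    rank_int,
    rank_real,
    rank_real_limit,
    scaling_check,
    smallK_count_bruteforce,
    stirling2,
)
from gridplace.separability import count_realizable


def partitions_into_k_blocks(n, k):
    """Independent brute-force oracle: count set partitions of n into k blocks."""

    def rec(elements, blocks):
        if not elements:
            return 1 if len(blocks) == k else 0
        if len(blocks) > k:
            return 0
        first, rest = elements[0], elements[1:]
        total = 0
        for i in range(len(blocks)):
            blocks[i].append(first)
            total += rec(rest, blocks)
            blocks[i].pop()
        blocks.append([first])
        total += rec(rest, blocks)
        blocks.pop()
        return total

    return rec(list(range(n)), [])


class TestStirling:
    @pytest.mark.parametrize("n,k", [(4, 2), (5, 3), (6, 2), (6, 4)])
    def test_matches_partition_enumeration(self, n, k):
        assert stirling2(n, k) == partitions_into_k_blocks(n, k)

    def test_boundary_values(self):
        assert stirling2(7, 1) == 1
        assert stirling2(7, 7) == 1
        with pytest.raises(ValueError):
            stirling2(3, 5)


class TestPolyBernoulli:
    def test_known_values(self):
        assert poly_bernoulli_neg(3, 2) == 46
        assert poly_bernoulli_neg(2, 2) == 14
        assert poly_bernoulli_neg(3, 3) == 230

    def test_symmetry(self):
        for n in range(7):
            for k in range(7):
                assert poly_bernoulli_neg(n, k) == poly_bernoulli_neg(k, n)


class TestTwoModuleCount:
    @pytest.mark.parametrize("lams", [(2, 2), (2, 3), (3, 3)])
    def test_closed_form_equals_lp_enumeration(self, lams):
        mo = make_modular_one_hot(list(lams))
        assert count_two_module(*lams).value == count_realizable(mo, "all")

    def test_degenerate_period_one_module(self):
        # a period-1 module adds a constant cell; all 2^n labelings realizable
        X = np.vstack([np.ones((1, 4)), np.eye(4)])
        assert count_two_module(1, 4).value == count_realizable(X, "all") == 16


class TestAsymptotics:
    def test_log_ratio_shrinks_monotonically(self):
        # the correction term decays slowly, so check the monotone trend
        # and that the log-domain gap becomes negligible relative to the
        # count itself
        gaps, rel = [], []
        for lam in range(2, 26, 4):
            exact = math.log(count_two_module(lam, lam).value)
            gap = abs(exact - log_asymptotic_two_module(lam))
            gaps.append(gap)
            rel.append(gap / exact)
        assert all(b < a for a, b in zip(gaps, gaps[1:]))
        assert rel[-1] < 0.01

    def test_growth_like_lambda_to_two_lambda(self):
        lam = 30
        assert log_asymptotic_two_module(lam) / (2 * lam * math.log(lam)) == (
            pytest.approx(1.0, rel=0.25)
        )

    def test_lam_one_finite_positive(self):
        assert 0 < asymptotic_two_module(1) < math.inf


class TestSmallK:
    def test_k1_count_equals_full_range(self):
        for periods in ([2, 3], [3, 4]):
            L = math.lcm(*periods)
            assert smallK_count_bruteforce(periods, 1).value == L

    def test_k2_count_grid_2_3(self):
        assert smallK_count_bruteforce([2, 3], 2).value == 9

    def test_scaling_exponent_near_M_plus_K_minus_one(self):
        # M=2, K=2: exact counts over growing periods, log-log slope ~ 3
        exponent, counts = scaling_check(2, [4, 6, 8, 10], 2)
        assert all(b > a for a, b in zip(counts, counts[1:]))
        assert exponent == pytest.approx(3.0, abs=0.5)


class TestCover:
    def test_all_dichotomies_when_P_at_most_N(self):
        for P, N in [(3, 5), (5, 5), (4, 8)]:
            assert cover_count(P, N) == 2**P

    def test_exactly_half_at_P_twice_N(self):
        for N in (2, 3, 5, 8):
            assert cover_count(2 * N, N) * 2 == 2 ** (2 * N)

    def test_c_4_3_against_random_halfspace_enumeration(self, rng):
        # oracle: enumerate sign patterns of homogeneous separators.  Random
        # directions alone can miss narrow cones, so also sweep directions
        # lying on each point's orthogonal plane and nudge them to either
        # side (every cell of the hyperplane arrangement has such a facet).
        X = rng.standard_normal((3, 4))
        signs = set()
        for _ in range(5000):
            w = rng.standard_normal(3)
            signs.add(tuple(w @ X > 0))
        for i in range(4):
            xi = X[:, i]
            u, v = np.linalg.svd(xi[None, :])[2][1:]
            for t in np.linspace(0.0, 2 * np.pi, 181):
                w0 = np.cos(t) * u + np.sin(t) * v
                for s in (1e-9, -1e-9):
                    signs.add(tuple((w0 + s * xi) @ X > 0))
        assert len(signs) == cover_count(4, 3) == 14

    def test_fraction_non_increasing_in_P(self):
        fr = [cover_count(P, 4) / 2**P for P in range(1, 15)]
        assert all(b <= a for a, b in zip(fr, fr[1:]))


class TestRank:
    @pytest.mark.parametrize(
        "periods,expected", [([3, 4], 6), ([2, 3], 4), ([4, 6], 8), ([5], 5)]
    )
    def test_closed_form_examples(self, periods, expected):
        assert rank_int(periods) == expected

    def test_matches_numeric_rank_on_random_period_sets(self, rng):
        for _ in range(30):
            M = int(rng.integers(1, 5))
            periods = [int(p) for p in rng.integers(2, 13, size=M)]
            cb = make_grid_codebook(periods)
            assert rank_int(periods) == np.linalg.matrix_rank(
                cb.patterns.astype(float)
            )

    def test_coprime_reduction_and_sandwich(self, rng):
        for _ in range(50):
            M = int(rng.integers(2, 5))
            periods = [int(p) for p in rng.integers(2, 13, size=M)]
            R = rank_int(periods)
            sigma = sum(periods)
            pair_gcd = sum(
                math.gcd(a, b) for a, b in itertools.combinations(periods, 2)
            )
            assert sigma - pair_gcd <= R <= sigma
            if all(
                math.gcd(a, b) == 1
                for a, b in itertools.combinations(periods, 2)
            ):
                assert R == sigma - M + 1

    def test_rank_real_reduces_to_rank_int_at_q1(self):
        assert rank_real([3.0, 4.0], 1) == rank_int([3, 4])

    def test_rank_real_ratio_bounded_and_rising(self, rng):
        for _ in range(10):
            M = int(rng.integers(2, 7))
            periods = rng.uniform(3, 20, size=M)
            curve = rank_real_limit(periods, [1, 2, 4, 8])
            ratios = [r for _, r in curve]
            assert all(r <= 1.0 + 1e-12 for r in ratios)
            assert ratios[-1] >= ratios[0]
            assert ratios[-1] > 0.9


class TestCapacityDD:
    def test_d1_is_sum_of_periods(self):
        assert capacity_dd([2, 3], 1) == 5

    def test_d2_sum_of_squares(self):
        assert capacity_dd([2, 3], 2) == 13

    def test_2d_codebook_rank_follows_rank_formula_on_squared_periods(self):
        # the 2D phase code is a modular-one-hot code with module sizes
        # lam^2, so its rank obeys the same inclusion-exclusion formula
        for periods in ([2, 3], [2, 5]):
            cb = make_grid_codebook_2d(periods)
            numeric = np.linalg.matrix_rank(cb.patterns.astype(float))
            assert numeric == rank_int([p * p for p in periods])
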