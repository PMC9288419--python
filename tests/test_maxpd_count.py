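"""Membership test, exact counting, closed forms, and bounds for maxPD
sets, cross-checked against exhaustive enumeration."""

import math

import pytest

from pdsets import (InvalidSizeError, bracket, branching_profile,
                    component_array, count_bounds, count_branching,
                    count_maxpd, count_maxpd_interval, generating_polynomial,
                    is_maxpd, optimal_k_perfect, perfect_tree_count,
                    ultrametric_heights)
from pdsets.fixtures import (brute_force, caterpillar, perfect_tree,
                             random_ultrametric)


class TestIsMaxPD:
    @pytest.mark.parametrize("A, expected", [
        ({"x3", "x4", "x7"}, True),
        ({"x2", "x3", "x6"}, True),
        ({"x5", "x6", "x7"}, False),  # the size-3 minPD set
        ({"x6", "x7"}, False),        # both members of one cherry
        ({"x1", "x4"}, True),
    ])
    def test_t1_examples(self, t1, t1_heights, A, expected):
        assert is_maxpd(t1, t1_heights, A) is expected

    def test_full_leaf_set_is_always_maxpd(self, t2, t2_heights):
        assert is_maxpd(t2, t2_heights, t2.leaf_labels())

    def test_agrees_with_brute_force_scores(self, t1, t1_heights):
        from itertools import combinations
        best, optimal = brute_force(t1, 3, mode="max")
        optimal = set(optimal)
        for combo in combinations(t1.leaf_labels(), 3):
            assert is_maxpd(t1, t1_heights, combo) is (
                frozenset(combo) in optimal)


class TestCountBranching:
    def test_t2_size4_product(self, t2, t2_heights):
        prof = branching_profile(t2, t2_heights)
        assert count_branching(prof.component_partition[4]) == 36

    def test_mammal_products(self, mammal):
        h = ultrametric_heights(mammal)
        prof = branching_profile(mammal, h)
        assert prof.branching_values == [1, 8, 16, 32]
        assert prof.component_partition[8].leaf_counts == [
            1, 8, 3, 2, 7, 3, 5, 3]
        assert count_branching(prof.component_partition[8]) == 15120
        assert sorted(prof.component_partition[16].leaf_counts) == sorted(
            [1, 2, 4, 1, 1, 3, 1, 1, 2, 1, 4, 3, 5, 1, 1, 1])
        assert count_branching(prof.component_partition[16]) == 2880

    def test_singleton_partition_counts_one(self, t2, t2_heights):
        prof = branching_profile(t2, t2_heights)
        assert count_branching(prof.component_partition[11]) == 1


class TestComponentArray:
    def test_t2_array_entries(self, t2, t2_heights):
        arr = component_array(t2, t2_heights, 5)
        assert (arr.k_minus, arr.k_plus) == (4, 7)
        as_sets = [[set(e) for e in col] for col in arr.columns]
        assert as_sets == [
            [{"x1", "x2"}, {"x3"}],
            [{"x10", "x9"}, {"x11"}],
            [{"x4"}],
            [{"x5", "x6"}, {"x7", "x8"}],
        ]
        grid = arr.size_grid()
        assert grid == [[2, 2, 1, 2], [1, 1, 0, 2]]

    def test_branching_k_gives_single_row(self, t2, t2_heights):
        arr = component_array(t2, t2_heights, 4)
        assert arr.n_columns == 4
        assert all(len(col) == 1 for col in arr.columns)

    def test_t3_array_shape(self, t3, t3_heights):
        arr = component_array(t3, t3_heights, 8)
        shapes = sorted(sorted(len(e) for e in col) for col in arr.columns)
        assert shapes == [[1, 1], [1, 1], [1, 2], [1, 2], [1, 2], [1, 2]]


class TestGeneratingPolynomial:
    def test_t2_polynomial(self, t2, t2_heights):
        arr = component_array(t2, t2_heights, 5)
        assert generating_polynomial(arr) == {4: 36, 5: 84, 6: 64, 7: 16}

    def test_t3_polynomial_matches_closed_product(self, t3, t3_heights):
        # (x^2+2x)^2 (2x^2+3x)^4 expanded independently with sympy
        import sympy

        x = sympy.symbols("x")
        ref = sympy.Poly(
            (x ** 2 + 2 * x) ** 2 * (2 * x ** 2 + 3 * x) ** 4, x).all_coeffs()
        ref_dict = {e: int(c) for e, c in
                    zip(range(len(ref) - 1, -1, -1), ref) if c != 0}
        arr = component_array(t3, t3_heights, 8)
        assert generating_polynomial(arr) == ref_dict

    def test_single_column_single_set(self, t2, t2_heights):
        arr = component_array(t2, t2_heights, 1)
        assert generating_polynomial(arr) == {1: 11}


class TestCountMaxPD:
    def test_t1_size3(self, t1, t1_heights):
        assert count_maxpd(t1, t1_heights, 3) == 20

    @pytest.mark.parametrize("k, expected", [
        (4, 36), (5, 84), (6, 64), (7, 16), (1, 11), (11, 1)])
    def test_t2_counts(self, t2, t2_heights, k, expected):
        assert count_maxpd(t2, t2_heights, k) == expected

    def test_t3_size8(self, t3, t3_heights):
        assert count_maxpd(t3, t3_heights, 8) == 1809

    def test_interval_answers_whole_bracket(self, t2, t2_heights):
        assert count_maxpd_interval(t2, t2_heights, 6) == {
            4: 36, 5: 84, 6: 64, 7: 16}

    def test_out_of_range(self, t1, t1_heights):
        with pytest.raises(InvalidSizeError):
            count_maxpd(t1, t1_heights, 0)

    @pytest.mark.parametrize("seed", range(40))
    def test_oracle_equivalence_random_trees(self, seed):
        """count and membership agree with exhaustive enumeration on random
        ultrametric trees including tied heights and multifurcations."""
        n = 4 + seed % 6
        t = random_ultrametric(n, seed=1000 + seed, tie_prob=0.3,
                               multifurcation_prob=0.25)
        h = ultrametric_heights(t)
        prof = branching_profile(t, h)
        for k in range(1, n + 1):
            best, optimal = brute_force(t, k, mode="max")
            assert count_maxpd(t, h, k, profile=prof) == len(optimal)

    def test_membership_oracle_random_tree(self):
        from itertools import combinations
        t = random_ultrametric(7, seed=77, tie_prob=0.4)
        h = ultrametric_heights(t)
        for k in (2, 3, 4):
            _, optimal = brute_force(t, k, mode="max")
            optimal = set(optimal)
            for combo in combinations(t.leaf_labels(), k):
                assert is_maxpd(t, h, combo) is (frozenset(combo) in optimal)


class TestPerfectTrees:
    @pytest.mark.parametrize("alpha, k, expected", [
        (4, 10, 1792),
        (5, 21, 8945664),
        (2, 1, 4), (2, 2, 4), (2, 3, 4),
        (3, 3, 32), (3, 5, 32),
        (4, 16, 1),
    ])
    def test_closed_form_values(self, alpha, k, expected):
        assert perfect_tree_count(alpha, k) == expected

    @pytest.mark.parametrize("alpha", [1, 2, 3, 4])
    def test_closed_form_matches_generating_function(self, alpha):
        t = perfect_tree(alpha)
        h = ultrametric_heights(t)
        prof = branching_profile(t, h)
        for k in range(1, 2 ** alpha + 1):
            assert perfect_tree_count(alpha, k) == count_maxpd(
                t, h, k, profile=prof)

    @pytest.mark.parametrize("n, expected", [
        (16, {10, 11}), (8, {5}), (4, {2, 3}), (32, {21}), (64, {42, 43})])
    def test_optimal_k(self, n, expected):
        assert optimal_k_perfect(n) == expected

    def test_optimal_k_really_maximises(self):
        # the formula names the maximisers at or above n/2; smaller k can
        # tie by the complement symmetry (e.g. k = 3 vs k = 5 at n = 8)
        for alpha in (2, 3, 4, 5):
            n = 2 ** alpha
            counts = {k: perfect_tree_count(alpha, k)
                      for k in range(1, n + 1)}
            best = max(counts.values())
            argmax = {k for k, c in counts.items() if c == best}
            formula = optimal_k_perfect(n)
            assert formula <= argmax
            assert argmax & set(range((n + 1) // 2, n + 1)) == formula

    def test_non_power_of_two_rejected(self):
        with pytest.raises(InvalidSizeError):
            optimal_k_perfect(12)

    def test_complement_of_small_maxpd_set_is_maxpd(self):
        t = perfect_tree(3)
        h = ultrametric_heights(t)
        labs = t.leaf_labels()
        for k in (1, 2, 3, 4):
            _, optimal = brute_force(t, k, mode="max")
            for A in optimal[:10]:
                comp = frozenset(labs) - A
                assert is_maxpd(t, h, comp)


class TestBounds:
    def test_bounds_values(self):
        lower, upper = count_bounds(11, 5)
        assert lower == 7
        assert upper == pytest.approx((11 / 5) ** 5)

    def test_nonbranching_k_may_exceed_upper(self, t2, t2_heights):
        _, upper = count_bounds(11, 5)
        assert count_maxpd(t2, t2_heights, 5) == 84 > upper

    def test_extreme_k(self):
        assert count_bounds(9, 9) == (1, 1.0)

    def test_caterpillars_attain_lower_bound(self):
        for n in (4, 6, 9):
            t = caterpillar(n)
            h = ultrametric_heights(t)
            prof = branching_profile(t, h)
            assert prof.branching_values == list(range(1, n + 1))
            for k in range(1, n + 1):
                assert count_maxpd(t, h, k, profile=prof) == n - k + 1

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_hold_at_branching_k(self, seed):
        n = 5 + seed % 5
        t = random_ultrametric(n, seed=500 + seed)  # binary, no ties
        h = ultrametric_heights(t)
        prof = branching_profile(t, h)
        for k in prof.branching_values:
            m = count_maxpd(t, h, k, profile=prof)
            lower, upper = count_bounds(n, k)
            assert lower <= m <= upper + 1e-9
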