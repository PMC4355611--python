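"""Unit and property tests for the diversity-statistic chain."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from popwin import stats
from conftest import (
    TOY_VALUES,
    distinct_pair_fraction,
    mean_pairwise_hamming,
    random_matrix,
    tajima_constants_exact,
    tajimas_d_exact,
)


class TestSegregatingSites:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([[1, 1], [1, 3]], 1),
            (np.ones((5, 4)), 0),
            ([[1, 5, 5, 3]], 1),      # missing codes ignored for S
            ([[5, 5, 5, 1]], 0),      # one non-missing allele: not segregating
            (TOY_VALUES, 3),
        ],
    )
    def test_counts(self, values, expected):
        assert stats.count_segregating_sites(np.asarray(values)) == expected

    def test_bounded_by_site_count(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            v = random_matrix(rng, allow_missing=True)
            assert 0 <= stats.count_segregating_sites(v) <= v.shape[0]


class TestHaplotypeTable:
    def test_groups_by_exact_string(self):
        # columns ACG, ACG, ATG
        v = np.array([[1, 1, 1], [2, 2, 4], [3, 3, 3]])
        t = stats.haplotype_table(v)
        assert t.n_haplotypes == 2
        assert t.counts.tolist() == [2, 1]
        np.testing.assert_allclose(t.frequencies, [2 / 3, 1 / 3])

    def test_identical_and_all_distinct(self):
        same = np.ones((4, 6), dtype=int)
        assert stats.haplotype_table(same).n_haplotypes == 1
        distinct = np.array([[1, 2, 3, 4]])
        t = stats.haplotype_table(distinct)
        assert t.n_haplotypes == 4
        np.testing.assert_allclose(t.frequencies, 0.25)

    def test_missing_is_a_fifth_symbol(self):
        v = np.array([[1, 5], [2, 2]])
        assert stats.haplotype_table(v).n_haplotypes == 2


class TestHaplotypeDiversity:
    def test_boundary_values(self):
        assert stats.haplotype_diversity(
            stats.haplotype_table(np.ones((3, 5), dtype=int)), 5
        ) == 0.0
        two = np.array([[1, 2]])
        assert stats.haplotype_diversity(stats.haplotype_table(two), 2) == 1.0

    def test_counts_211(self):
        # N=4 with counts {2,1,1}: 5 of the 6 unordered pairs differ
        v = np.array([[1, 1, 2, 3]])
        hd = stats.haplotype_diversity(stats.haplotype_table(v), 4)
        assert hd == pytest.approx(5 / 6, abs=1e-12)

    def test_undefined_below_two(self):
        with pytest.raises(ValueError):
            stats.haplotype_diversity(
                stats.haplotype_table(np.ones((1, 2), dtype=int)), 1
            )


class TestSiteDiversity:
    @pytest.mark.parametrize(
        "codes, expected",
        [
            ([1, 1, 2, 2], 2 / 3),     # 4 of 6 pairs differ
            ([1, 1, 1], 0.0),
            ([1, 2, 3], 1.0),          # tri-allelic: every pair differs
            ([1, 5, 5, 3], 1.0),       # missing excluded, n_eff = 2
        ],
    )
    def test_examples(self, codes, expected):
        assert stats.site_diversity(np.asarray(codes)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_fewer_than_two_alleles_is_an_error(self):
        with pytest.raises(ValueError):
            stats.site_diversity(np.array([1, 5, 5]))

    def test_k_allele_upper_bound(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 12))
            codes = rng.integers(1, 5, size=n)
            k = len(set(codes.tolist()))
            bound = n / (n - 1) * (1 - 1 / k)
            assert 0.0 <= stats.site_diversity(codes) <= bound + 1e-12


class TestWindowPi:
    def test_toy_window(self):
        big_pi, pi = stats.window_pi(TOY_VALUES, 3)
        assert big_pi == pytest.approx(5 / 3, abs=1e-12)
        assert pi == pytest.approx(5 / 9, abs=1e-12)

    def test_empty_window(self):
        assert stats.window_pi(np.empty((0, 4), dtype=int), 100) == (0.0, 0.0)

    def test_single_site_span_one(self):
        big_pi, pi = stats.window_pi(np.array([[1, 1, 2, 2]]), 1)
        assert big_pi == pi == pytest.approx(2 / 3, abs=1e-12)

    def test_sites_without_estimator_are_excluded(self):
        v = np.array([[1, 5, 5, 5], [1, 2, 1, 2]])
        pi_i, excluded = stats.site_diversities(v)
        assert excluded == 1
        assert pi_i[0] == 0.0


class TestTajimaChain:
    @pytest.mark.parametrize("n", [2, 3, 4, 5, 10, 40, 100])
    def test_constants_match_exact_rational_oracle(self, n):
        got = stats.tajima_constants(n)
        exact = tajima_constants_exact(n)
        for name, val in exact.items():
            assert getattr(got, name) == pytest.approx(
                float(val), rel=1e-12
            ), name

    def test_constants_n2(self):
        c = stats.tajima_constants(2)
        assert (c.a1, c.a2, c.b1) == (1.0, 1.0, 1.0)

    def test_watterson(self):
        assert stats.watterson_theta(0, 9) == 0.0
        assert stats.watterson_theta(3, 4) == pytest.approx(18 / 11, rel=1e-12)
        assert stats.watterson_theta(1, 2) == 1.0

    def test_d_undefined_at_s0(self):
        assert stats.tajimas_d(0.0, 0, 10) is None

    def test_d_zero_numerator(self):
        theta = stats.watterson_theta(4, 6)
        assert stats.tajimas_d(theta, 4, 6) == pytest.approx(0.0, abs=1e-15)

    def test_toy_d_matches_end_to_end_oracle(self):
        d = stats.tajimas_d(5 / 3, 3, 4)
        assert d == pytest.approx(
            tajimas_d_exact(Fraction(5, 3), 3, 4), abs=1e-9
        )

    def test_requires_two_haplotypes(self):
        with pytest.raises(ValueError):
            stats.tajima_constants(1)


class TestPairwiseOracleProperty:
    """Π and Hd must agree with brute-force pair enumeration."""

    def test_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            v = random_matrix(rng)
            big_pi, _ = stats.window_pi(v, v.shape[0])
            assert big_pi == pytest.approx(
                mean_pairwise_hamming(v), abs=1e-12
            )
            hd = stats.haplotype_diversity(
                stats.haplotype_table(v), v.shape[1]
            )
            assert hd == pytest.approx(distinct_pair_fraction(v), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        arrays(np.int8, st.tuples(st.integers(1, 8), st.integers(2, 6)),
               elements=st.integers(1, 4))
    )
    def test_hypothesis_matrices(self, v):
        big_pi, _ = stats.window_pi(v, v.shape[0])
        assert big_pi == pytest.approx(mean_pairwise_hamming(v), abs=1e-12)
        hd = stats.haplotype_diversity(stats.haplotype_table(v), v.shape[1])
        assert hd == pytest.approx(distinct_pair_fraction(v), abs=1e-12)


class TestRelabelingInvariance:
    def test_base_permutation_changes_nothing(self):
        from itertools import permutations

        rng = np.random.default_rng(5)
        v = random_matrix(rng, max_n=6, max_m=8, allow_missing=True)
        n = v.shape[1]
        s0 = stats.count_segregating_sites(v)
        pi0, _ = stats.window_pi(v, v.shape[0])
        hd0 = stats.haplotype_diversity(stats.haplotype_table(v), n)
        d0 = stats.tajimas_d(pi0, s0, n)
        for perm in permutations((1, 2, 3, 4)):
            lut = np.array([0, *perm, 5], dtype=np.int8)
            w = lut[v]
            assert stats.count_segregating_sites(w) == s0
            pi1, _ = stats.window_pi(w, w.shape[0])
            assert pi1 == pytest.approx(pi0, abs=1e-12)
            hd1 = stats.haplotype_diversity(stats.haplotype_table(w), n)
            assert hd1 == pytest.approx(hd0, abs=1e-12)
            d1 = stats.tajimas_d(pi1, stats.count_segregating_sites(w), n)
            if d0 is None:
                assert d1 is None
            else:
                assert d1 == pytest.approx(d0, abs=1e-12)


def test_monomorphic_panel_degenerates_cleanly():
    """All-identical columns: S=0, Hd=0, Π=0 and D undefined."""
    v = np.full((6, 5), 3, dtype=np.int8)
    assert stats.count_segregating_sites(v) == 0
    t = stats.haplotype_table(v)
    assert t.n_haplotypes == 1
    assert stats.haplotype_diversity(t, 5) == 0.0
    big_pi, pi = stats.window_pi(v, 6)
    assert big_pi == pi == 0.0
    assert stats.tajimas_d(big_pi, 0, 5) is None


def test_global_haplotype_frequencies_window_independent(toy_values):
    t = stats.global_haplotype_frequencies(toy_values)
    assert t.n_haplotypes == 4
    assert t.total == 4
    np.testing.assert_allclose(t.frequencies.sum(), 1.0, atol=1e-12)
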