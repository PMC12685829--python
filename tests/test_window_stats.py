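"""Nucleotide diversity, Tajima's D, Hudson F_ST, pi-ratio and LD r-squared."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from sweeproh import (
    GenomeLayout,
    PopulationSpec,
    compute_r2,
    fst_windows,
    hudson_fst_site,
    ld_decay,
    make_windows,
    pi_ratio_windows,
    pi_windows,
    site_pi,
    tajimas_d,
)

from conftest import make_matrix, random_phased_matrix


class TestSitePi:
    @pytest.mark.parametrize(
        "alt,n,expected",
        [
            (1, 2, 1.0),  # one pair, one difference
            (0, 2, 0.0),  # monomorphic
            (2, 4, 2.0 / 3.0),  # 4 of 6 haplotype pairs differ
        ],
    )
    def test_matches_mean_pairwise_difference(self, alt, n, expected):
        assert site_pi(alt, n) == pytest.approx(expected, abs=1e-15)

    def test_brute_force_over_haplotype_pairs(self):
        # enumerate all haplotype pairs for every (alt, n) configuration
        for n in (2, 4, 6, 9):
            for alt in range(n + 1):
                haps = [1] * alt + [0] * (n - alt)
                pairs = list(itertools.combinations(haps, 2))
                mean_diff = sum(a != b for a, b in pairs) / len(pairs)
                assert site_pi(alt, n) == pytest.approx(mean_diff, abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(n=st_.integers(2, 60), data=st_.data())
    def test_bounds_and_symmetry(self, n, data):
        """site_pi lies in [0, n/(2(n-1))·... bounded by ~0.5·n/(n-1)] and is
        symmetric in ref/alt labelling."""
        alt = data.draw(st_.integers(0, n))
        value = site_pi(alt, n)
        assert 0.0 <= value <= 0.5 * n / (n - 1) + 1e-12
        assert value == pytest.approx(site_pi(n - alt, n), abs=1e-15)

    def test_too_few_alleles_rejected(self):
        with pytest.raises(ValueError):
            site_pi(0, 1)


def brute_pi_per_bp(matrix, sample_idx, window):
    """Oracle: mean per-bp Hamming distance over all haplotype pairs."""
    haps = []
    for s in sample_idx:
        haps.append(matrix.haplotypes[:, s, 0])
        haps.append(matrix.haplotypes[:, s, 1])
    in_win = (matrix.pos >= window.start) & (matrix.pos < window.end)
    total = 0.0
    pairs = list(itertools.combinations(range(len(haps)), 2))
    for a, b in pairs:
        total += np.sum(haps[a][in_win] != haps[b][in_win])
    return total / len(pairs) / window.length


class TestPiWindows:
    def make_spec(self, matrix):
        return PopulationSpec({s: "p" for s in matrix.sample_ids})

    def test_single_site_two_haplotypes(self):
        # one 100 kb window holding one site where 1 of 4 haplotypes carries alt
        haps = np.array([[[0, 0], [0, 1]]], dtype=np.int8)
        m = make_matrix(haps.sum(axis=2), pos=[500], haplotypes=haps)
        layout = GenomeLayout(("chr1",), (100_000,), (True,))
        grid = make_windows(layout, 100_000, 100_000)
        stats = pi_windows(m, self.make_spec(m), grid, tajima=False)
        # n = 4 alleles, alt count 1: site_pi = 2*(1/4)*(3/4)*(4/3) = 0.5
        assert stats[0].pi_by_pop["p"] == pytest.approx(0.5 / 100_000)

    def test_no_variation_gives_zero_everywhere(self):
        m = make_matrix(np.zeros((30, 4), dtype=np.int8))
        layout = GenomeLayout(("chr1",), (50_000,), (True,))
        grid = make_windows(layout, 10_000, 5_000)
        stats = pi_windows(m, self.make_spec(m), grid, tajima=False)
        assert all(st.pi_by_pop["p"] == 0.0 for st in stats)

    def test_oracle_equivalence_on_random_matrices(self):
        rng = np.random.default_rng(42)
        layout = GenomeLayout(("chr1",), (100_000,), (True,))
        grid = make_windows(layout, 50_000, 25_000)
        for _ in range(25):
            n_samples = int(rng.integers(2, 11))
            m = random_phased_matrix(rng, n_samples=n_samples, n_sites=int(rng.integers(5, 200)))
            stats = pi_windows(m, self.make_spec(m), grid, tajima=False)
            for st in stats:
                oracle = brute_pi_per_bp(m, range(n_samples), st.window)
                assert st.pi_by_pop["p"] == pytest.approx(oracle, abs=1e-12)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        m = random_phased_matrix(rng, n_samples=6, n_sites=80)
        layout = GenomeLayout(("chr1",), (100_000,), (True,))
        grid = make_windows(layout, 100_000, 100_000)
        spec = self.make_spec(m)
        stats = pi_windows(m, spec, grid)
        shuffled = m.subset_samples(list(m.sample_ids)[::-1])
        stats2 = pi_windows(shuffled, spec, grid)
        assert stats[0].pi_by_pop["p"] == pytest.approx(stats2[0].pi_by_pop["p"], abs=1e-15)
        assert stats[0].tajima_d_by_pop["p"] == pytest.approx(
            stats2[0].tajima_d_by_pop["p"], abs=1e-12
        )


def oracle_tajimas_d(alt_counts, n):
    """Independent constant-by-constant evaluation of Tajima's D."""
    S = sum(1 for a in alt_counts if 0 < a < n)
    if S == 0:
        return None
    pi = 0.0
    for a in alt_counts:
        p = a / n
        pi += 2.0 * p * (1 - p) * n / (n - 1)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        assert tajimas_d(np.array([0, 0, 10]), 10) is None

    def test_exact_zero_numerator(self):
        # n=4: a1 = 11/6; 8 singletons (pi 0.5 each) + 3 doubletons (pi 2/3)
        # give pi_sum = 6 = S/a1 with S = 11, hence D = 0 exactly
        alt = np.array([1] * 8 + [2] * 3)
        assert tajimas_d(alt, 4) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_evaluation(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            S = int(rng.integers(1, 20))
            alt = rng.integers(0, n + 1, size=S)
            expected = oracle_tajimas_d(alt.tolist(), n)
            got = tajimas_d(alt, n)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-10)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            tajimas_d(np.array([1]), 3)


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        n, d = hudson_fst_site(1.0, 10, 0.0, 10)
        assert n / d == pytest.approx(1.0)
        n, d = hudson_fst_site(1.0, 4, 0.0, 200)
        assert n / d == pytest.approx(1.0)

    def test_equal_frequencies_negative_site_estimate(self):
        n, d = hudson_fst_site(0.5, 10, 0.5, 10)
        assert n == pytest.approx(-2 * 0.25 / 9)
        assert d == pytest.approx(0.5)
        assert n / d == pytest.approx(-0.1111, abs=1e-3)

    def test_monomorphic_contributes_nothing(self):
        assert hudson_fst_site(0.0, 10, 0.0, 10) == (0.0, 0.0)
        assert hudson_fst_site(1.0, 10, 1.0, 10) == (0.0, 0.0)

    def _two_pop(self, g_a, g_b):
        g = np.hstack([g_a, g_b]).astype(np.int8)
        m = make_matrix(g)
        spec = PopulationSpec(
            {s: ("a" if i < g_a.shape[1] else "b") for i, s in enumerate(m.sample_ids)}
        )
        return m, spec

    def test_window_of_fixed_differences_is_one(self):
        g_a = np.full((10, 4), 2, dtype=np.int8)
        g_b = np.zeros((10, 4), dtype=np.int8)
        m, spec = self._two_pop(g_a, g_b)
        layout = GenomeLayout(("chr1",), (100_000,), (True,))
        grid = make_windows(layout, 100_000, 100_000)
        stats = fst_windows(m, spec, "a", "b", grid)
        assert stats[0].fst == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(21)
        p = rng.uniform(0.1, 0.9, size=200)
        g_a = (rng.random((200, 25, 2)) < p[:, None, None]).sum(axis=2)
        g_b = (rng.random((200, 25, 2)) < p[:, None, None]).sum(axis=2)
        m, spec = self._two_pop(g_a, g_b)
        layout = GenomeLayout(("chr1",), (250_000,), (True,))
        grid = make_windows(layout, 250_000, 250_000)
        stats = fst_windows(m, spec, "a", "b", grid)
        assert abs(stats[0].fst) < 0.05

    def test_ratio_of_averages_matches_hand_sum(self):
        g_a = np.array([[0, 1, 2], [2, 2, 1], [0, 0, 1]], dtype=np.int8)
        g_b = np.array([[2, 2, 2], [0, 1, 0], [0, 0, 0]], dtype=np.int8)
        m, spec = self._two_pop(g_a, g_b)
        num = den = 0.0
        for v in range(3):
            p1 = g_a[v].sum() / 6.0
            p2 = g_b[v].sum() / 6.0
            n_, d_ = hudson_fst_site(p1, 6, p2, 6)
            num += n_
            den += d_
        layout = GenomeLayout(("chr1",), (100_000,), (True,))
        grid = make_windows(layout, 100_000, 100_000)
        stats = fst_windows(m, spec, "a", "b", grid)
        assert stats[0].fst == pytest.approx(num / den, abs=1e-12)

    def test_ref_alt_swap_invariance(self):
        rng = np.random.default_rng(4)
        g_a = rng.integers(0, 3, size=(50, 6), dtype=np.int8)
        g_b = rng.integers(0, 3, size=(50, 6), dtype=np.int8)
        m, spec = self._two_pop(g_a, g_b)
        layout = GenomeLayout(("chr1",), (100_000,), (True,))
        grid = make_windows(layout, 100_000, 100_000)
        swapped = make_matrix((2 - np.hstack([g_a, g_b])).astype(np.int8))
        st1 = fst_windows(m, spec, "a", "b", grid)
        spec2 = PopulationSpec(
            {s: ("a" if i < 6 else "b") for i, s in enumerate(swapped.sample_ids)}
        )
        st2 = fst_windows(swapped, spec2, "a", "b", grid)
        assert st1[0].fst == pytest.approx(st2[0].fst, abs=1e-12)
        p1 = pi_windows(m, spec, grid, tajima=False)
        p2 = pi_windows(swapped, spec2, grid, tajima=False)
        for pop in ("a", "b"):
            assert p1[0].pi_by_pop[pop] == pytest.approx(p2[0].pi_by_pop[pop], abs=1e-15)


class TestPiRatio:
    def _stats(self, pi_ref, pi_tgt):
        from sweeproh.windowstats import WindowStat
        from sweeproh import GenomicInterval

        st = WindowStat(window=GenomicInterval("c", 0, 1000))
        st.pi_by_pop = {"ref": pi_ref, "tgt": pi_tgt}
        return [st]

    def test_simple_division(self):
        (st,) = pi_ratio_windows(self._stats(0.0032, 0.0010), "ref", "tgt")
        assert st.pi_ratio == pytest.approx(3.2)

    def test_zero_target_pi_undefined(self):
        (st,) = pi_ratio_windows(self._stats(0.001, 0.0), "ref", "tgt")
        assert st.pi_ratio is None


class TestComputeR2:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 0, 2, 1], dtype=np.int8)
        assert compute_r2(g, g) == pytest.approx(1.0)

    def test_coupling_haplotypes_complete_ld(self):
        h1 = np.array([1, 1, 1, 0, 0, 0], dtype=np.int8)
        assert compute_r2(h1, h1.copy(), phased=True) == pytest.approx(1.0)

    def test_haplotype_count_arithmetic(self):
        # AB=4, Ab=1, aB=1, ab=4: D = 0.4 - 0.25 = 0.15, r2 = 0.15^2/0.5^4
        h1 = np.array([1] * 5 + [0] * 5, dtype=np.int8)
        h2 = np.array([1] * 4 + [0] + [1] + [0] * 4, dtype=np.int8)
        assert compute_r2(h1, h2, phased=True) == pytest.approx(0.36)

    def test_monomorphic_undefined(self):
        assert compute_r2(np.zeros(6, np.int8), np.array([0, 1, 2, 0, 1, 2], np.int8)) is None

    def test_missing_excluded_pairwise(self):
        g1 = np.array([0, 1, 2, -1, 2], dtype=np.int8)
        g2 = np.array([0, 1, 2, 2, -1], dtype=np.int8)
        assert compute_r2(g1, g2) == pytest.approx(1.0)


class TestLdDecay:
    def test_duplicated_columns_full_ld(self):
        rng = np.random.default_rng(6)
        col = rng.integers(0, 3, size=40).astype(np.int8)
        g = np.vstack([col] * 10)
        m = make_matrix(g, pos=np.arange(10) * 5_000)
        curve = ld_decay(m, max_distance=50_000, maf_min=0.05, n_bins=10)
        occupied = curve.pair_counts > 0
        assert occupied.any()
        assert np.allclose(curve.mean_r2[occupied], 1.0)

    def test_pairs_beyond_max_distance_excluded(self):
        col = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=np.int8)
        m = make_matrix(np.vstack([col, col]), pos=[0, 1_000_001])
        curve = ld_decay(m, max_distance=1_000_000, maf_min=0.0, n_bins=4)
        assert curve.pair_counts.sum() == 0
        m2 = make_matrix(np.vstack([col, col]), pos=[0, 1_000_000])
        curve2 = ld_decay(m2, max_distance=1_000_000, maf_min=0.0, n_bins=4)
        assert curve2.pair_counts.sum() == 1  # inclusive boundary

    def test_unlinked_sites_low_flat_r2(self):
        rng = np.random.default_rng(30)
        p = rng.uniform(0.2, 0.8, size=120)
        g = (rng.random((120, 50, 2)) < p[:, None, None]).sum(axis=2).astype(np.int8)
        m = make_matrix(g, pos=np.arange(120) * 2_000)
        curve = ld_decay(m, max_distance=240_000, maf_min=0.05, n_bins=6)
        occupied = curve.pair_counts > 0
        # E[r2] ~ 1/n = 0.02 for unlinked loci
        assert np.nanmean(curve.mean_r2[occupied]) < 0.05
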