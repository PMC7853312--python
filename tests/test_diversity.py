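from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest

from pikapop.diversity import (
    compute_saf,
    estimate_folded_sfs,
    fold_saf,
    per_site_thetas,
    population_diversity,
    tajima_constants,
    windowed_tajima,
)
from pikapop.synthetic_data import simulate_sfs_sites


def bruteforce_saf(likelihoods):
    """Enumerate all genotype configurations: independent SAF oracle.

    P(data | j) = sum over configs with total allele count j of
    prod_i GL_i(g_i) * prod_i C(2, g_i) / C(2n, j).
    """
    n_ind = likelihoods.shape[0]
    n = 2 * n_ind
    out = np.zeros(n + 1)
    for config in product(range(3), repeat=n_ind):
        j = sum(config)
        w = 1.0
        for i, g in enumerate(config):
            w *= likelihoods[i, g] * comb(2, g)
        out[j] += w
    out /= np.array([comb(n, j) for j in range(n + 1)])
    return out / out.max()


def certain_gl_from_genotypes(genotypes, certain_gl):
    return certain_gl(genotypes)


class TestSaf:
    def test_certain_single_het_concentrates_at_one(self, certain_gl):
        gl = certain_gl(np.array([[1], [0]]), floor=0.0)
        saf = compute_saf(gl)[0]
        assert saf[1] == pytest.approx(1.0)
        others = np.delete(saf, 1)
        assert others.max() == 0.0

    def test_all_hom_ref_concentrates_at_zero(self, certain_gl):
        gl = certain_gl(np.zeros((3, 2), int), floor=0.0)
        saf = compute_saf(gl)
        assert np.allclose(saf[:, 0], 1.0) and saf[:, 1:].max() == 0.0

    def test_dp_matches_bruteforce_enumeration(self, certain_gl):
        rng = np.random.default_rng(0)
        for n_ind in (2, 3, 4):
            gl = certain_gl(np.zeros((n_ind, 20), int))
            gl.likelihoods = rng.random((n_ind, 20, 3)) + 1e-3
            gl.likelihoods /= gl.likelihoods.max(axis=2, keepdims=True)
            saf = compute_saf(gl)
            for l in range(20):
                oracle = bruteforce_saf(gl.likelihoods[:, l, :])
                np.testing.assert_allclose(saf[l], oracle, rtol=1e-10)

    def test_flat_likelihoods_match_bruteforce(self, certain_gl):
        gl = certain_gl(np.zeros((3, 1), int))
        gl.likelihoods = np.ones((3, 1, 3))
        saf = compute_saf(gl)[0]
        np.testing.assert_allclose(saf, bruteforce_saf(np.ones((3, 3))), rtol=1e-12)

    def test_single_individual_rejected(self, certain_gl):
        gl = certain_gl(np.zeros((1, 3), int))
        with pytest.raises(ValueError, match="two individuals"):
            compute_saf(gl)


class TestFoldedSfs:
    def test_certainty_limit_equals_count_histogram(self):
        rng = np.random.default_rng(1)
        n_ind = 10
        counts = rng.integers(0, 2 * n_ind + 1, size=500)
        gl, genotypes = simulate_sfs_sites(n_ind, counts, mean_depth=1000, seed=2)
        phi = estimate_folded_sfs(compute_saf(gl))
        n = 2 * n_ind
        minor = np.minimum(genotypes.sum(0), n - genotypes.sum(0))
        hist = np.bincount(minor, minlength=n // 2 + 1) / len(counts)
        np.testing.assert_allclose(phi, hist, atol=1e-9)

    def test_monomorphic_certain_sites_put_mass_at_zero(self, certain_gl):
        gl = certain_gl(np.zeros((4, 150), int))
        phi = estimate_folded_sfs(compute_saf(gl))
        assert phi[0] == pytest.approx(1.0, abs=1e-9)

    def test_no_sites_rejected(self):
        with pytest.raises(ValueError):
            estimate_folded_sfs(np.zeros((0, 5)))

    def test_neutral_coalescent_spectrum_matches_theory(self):
        # msprime as an independent coalescent oracle: the folded SFS of a
        # neutral constant-size population follows ~ 1/j + 1/(n-j).
        # One site per replicate genealogy: linked sites share a tree and
        # would break the chi-square independence assumption.
        msprime = pytest.importorskip("msprime")
        from scipy.stats import chisquare

        n_ind = 10
        counts = []
        reps = msprime.sim_ancestry(
            samples=n_ind, population_size=10_000, sequence_length=1_000,
            recombination_rate=0, num_replicates=1200, random_seed=7,
        )
        for i, ts in enumerate(reps):
            mts = msprime.sim_mutations(ts, rate=2e-7, random_seed=100 + i)
            G = mts.genotype_matrix()  # sites x 2n
            if len(G) == 0:
                continue
            bi = np.flatnonzero(G.max(axis=1) == 1)  # skip recurrent mutations
            if len(bi) == 0:
                continue
            j = int(G[bi[0]].sum())
            if 0 < j < 2 * n_ind:
                counts.append(j)
        counts = np.array(counts)
        assert len(counts) > 800
        gl, _ = simulate_sfs_sites(n_ind, counts, mean_depth=60, seed=9)
        phi = estimate_folded_sfs(compute_saf(gl))
        n = 2 * n_ind
        classes = np.arange(1, n // 2 + 1)
        expect = np.array([
            1 / c + (1 / (n - c) if n - c != c else 0) for c in classes
        ])
        expect /= expect.sum()
        observed = phi[1:] / phi[1:].sum() * len(counts)
        _, p = chisquare(observed, expect * len(counts))
        assert p > 0.01


class TestThetas:
    def test_singleton_site_hand_computation(self, certain_gl):
        g = np.zeros((2, 1), int)
        g[0, 0] = 1  # one het among two diploids: n=4, j=1
        gl = certain_gl(g)
        saf = compute_saf(gl)
        phi = np.array([0.5, 0.25, 0.25])
        track = per_site_thetas(saf, phi)
        assert track["pi"][0] == pytest.approx(1 * 3 / 6, abs=1e-9)
        assert track["theta_w"][0] == pytest.approx(1 / (11 / 6), abs=1e-9)

    def test_monomorphic_certain_contributions_zero(self, certain_gl):
        gl = certain_gl(np.zeros((2, 3), int))
        track = per_site_thetas(compute_saf(gl), np.array([0.9, 0.05, 0.05]))
        assert track["pi"].max() < 1e-9 and track["theta_w"].max() < 1e-9

    def test_mean_pi_with_one_doubleton(self, certain_gl):
        g = np.zeros((2, 100), int)
        g[0, 0] = 1
        g[1, 0] = 1  # one doubleton (j=2, n=4) among 100 sites
        gl = certain_gl(g)
        saf = compute_saf(gl)
        phi = estimate_folded_sfs(saf)
        track = per_site_thetas(saf, phi)
        assert track["pi"].mean() == pytest.approx((2 * 2 / 6) / 100, abs=1e-9)

    def test_prior_length_mismatch_rejected(self, certain_gl):
        gl = certain_gl(np.zeros((3, 2), int))
        with pytest.raises(ValueError, match="match"):
            per_site_thetas(compute_saf(gl), np.ones(17) / 17)

    def test_certainty_limit_pi_equals_pairwise_difference(self):
        rng = np.random.default_rng(3)
        n_ind = 6
        counts = rng.integers(0, 2 * n_ind + 1, size=300)
        gl, genotypes = simulate_sfs_sites(n_ind, counts, mean_depth=1000, seed=4)
        saf = compute_saf(gl)
        track = per_site_thetas(saf, estimate_folded_sfs(saf), sites=gl.sites)
        n = 2 * n_ind
        j = genotypes.sum(axis=0)
        direct = j * (n - j) / (n * (n - 1) / 2)
        np.testing.assert_allclose(track["pi"].to_numpy(), direct, atol=1e-9)


class TestTajimaConstants:
    def test_n4_closed_forms(self):
        c = tajima_constants(4)
        assert c.a1 == pytest.approx(11 / 6, abs=1e-12)
        assert c.a2 == pytest.approx(49 / 36, abs=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            tajima_constants(2)

    def test_n10_matches_exact_fraction_oracle(self):
        # independent implementation with exact rational arithmetic
        n = 10
        a1 = Fraction(sum(Fraction(1, i) for i in range(1, n)))
        a2 = Fraction(sum(Fraction(1, i * i) for i in range(1, n)))
        b1 = Fraction(n + 1, 3 * (n - 1))
        b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        got = tajima_constants(n)
        for name, exact in zip(
            ("a1", "a2", "b1", "b2", "c1", "c2", "e1", "e2"),
            (a1, a2, b1, b2, c1, c2, e1, e2),
        ):
            assert getattr(got, name) == pytest.approx(float(exact), abs=1e-12)


class TestWindowedTajima:
    def test_balanced_window_gives_zero(self):
        track = pd.DataFrame(
            {"scaffold": ["s"] * 3, "pos": [10, 20, 30],
             "pi": [0.2, 0.3, 0.1], "theta_w": [0.2, 0.3, 0.1]}
        )
        table, mean_d = windowed_tajima(track, n=8)
        assert table["tajima_d"][0] == pytest.approx(0.0, abs=1e-12)

    def test_single_singleton_window_matches_hand_value(self, certain_gl):
        g = np.zeros((2, 1), int)
        g[0, 0] = 1
        gl = certain_gl(g)
        saf = compute_saf(gl)
        track = per_site_thetas(saf, np.array([0.5, 0.3, 0.2]), sites=gl.sites)
        table, _ = windowed_tajima(track, n=4)
        # hand computation: S_pi = 1/2, S_theta = 6/11, S = 1,
        # D = (1/2 - 6/11) / sqrt(e1)
        c = tajima_constants(4)
        expected = (0.5 - 6 / 11) / np.sqrt(c.e1)
        assert table["tajima_d"][0] == pytest.approx(expected, abs=1e-9)

    def test_empty_windows_emit_nothing(self, certain_gl):
        gl = certain_gl(np.zeros((2, 5), int), floor=0.0)
        saf = compute_saf(gl)
        track = per_site_thetas(saf, np.array([0.98, 0.01, 0.01]), sites=gl.sites)
        table, mean_d = windowed_tajima(track, n=4)
        # monomorphic with certainty: S_theta = 0 everywhere -> no windows
        assert len(table) == 0 and np.isnan(mean_d)

    def test_spectrum_direction(self):
        # excess of common variants -> positive D; excess of singletons -> negative
        rng = np.random.default_rng(6)
        n_ind = 10
        n = 2 * n_ind
        common = rng.integers(6, n - 5, size=400)
        pos = np.sort(rng.choice(500_000, 400, replace=False)) + 1
        gl, _ = simulate_sfs_sites(n_ind, common, positions=pos, mean_depth=30, seed=7)
        saf = compute_saf(gl)
        track = per_site_thetas(saf, estimate_folded_sfs(saf), sites=gl.sites)
        _, d_common = windowed_tajima(track, n=n)
        singles = np.ones(400, int)
        gl2, _ = simulate_sfs_sites(n_ind, singles, positions=pos, mean_depth=30, seed=8)
        saf2 = compute_saf(gl2)
        track2 = per_site_thetas(saf2, estimate_folded_sfs(saf2), sites=gl2.sites)
        _, d_single = windowed_tajima(track2, n=n)
        assert d_common > 0 > d_single


class TestFoldSymmetry:
    def test_allele_relabeling_leaves_estimates_unchanged(self):
        rng = np.random.default_rng(9)
        n_ind = 5
        counts = rng.integers(0, 2 * n_ind + 1, size=200)
        gl, _ = simulate_sfs_sites(n_ind, counts, mean_depth=15, seed=10)
        swapped = gl.subset_sites(np.ones(gl.n_sites, bool))
        swapped.likelihoods = swapped.likelihoods[:, :, ::-1].copy()
        for a, b in ((gl, swapped),):
            saf_a, saf_b = compute_saf(a), compute_saf(b)
            np.testing.assert_allclose(fold_saf(saf_a), fold_saf(saf_b), atol=1e-12)
            phi_a, phi_b = estimate_folded_sfs(saf_a), estimate_folded_sfs(saf_b)
            np.testing.assert_allclose(phi_a, phi_b, atol=1e-9)
            ta = per_site_thetas(saf_a, phi_a, sites=a.sites)
            tb = per_site_thetas(saf_b, phi_b, sites=b.sites)
            np.testing.assert_allclose(ta["pi"], tb["pi"], atol=1e-9)
            np.testing.assert_allclose(ta["theta_w"], tb["theta_w"], atol=1e-9)
            da = windowed_tajima(ta, n=2 * n_ind)[1]
            db = windowed_tajima(tb, n=2 * n_ind)[1]
            assert da == pytest.approx(db, abs=1e-9)


class TestPopulationDiversity:
    def test_summary_fields_consistent(self):
        rng = np.random.default_rng(11)
        counts = np.concatenate([np.zeros(300, int), rng.integers(1, 10, 60)])
        rng.shuffle(counts)
        gl, _ = simulate_sfs_sites(5, counts, mean_depth=20, seed=12)
        summary, windows, phi = population_diversity(gl, population="test")
        assert summary.n_sites == 360
        assert summary.n_windows == len(windows)
        assert summary.pi > 0 and summary.theta_w > 0
        assert phi.sum() == pytest.approx(1.0, abs=1e-6)
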