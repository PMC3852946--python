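"""Kingman coalescent simulator and the null distributions built on it."""

import numpy as np
import pytest

from sweepstakes import sumstats
from sweepstakes.coalescent import (NullCache, estimate_Heq,
                                    infinite_sites_counts,
                                    null_M_distribution, simulate_genealogy,
                                    smm_locus, tajima_null_distribution)


def harmonic(n):
    return float(np.sum(1.0 / np.arange(1, n + 1)))


class TestGenealogy:
    def test_pair_height_is_standard_exponential(self, rng):
        heights = [simulate_genealogy(2, rng).branch_length[0]
                   for _ in range(4000)]
        assert np.mean(heights) == pytest.approx(1.0, abs=4 / np.sqrt(4000))

    def test_total_length_matches_harmonic_sum(self, rng):
        n = 20
        expect = 2 * harmonic(n - 1)
        tl = [simulate_genealogy(n, rng).total_length for _ in range(3000)]
        se = np.std(tl, ddof=1) / np.sqrt(len(tl))
        assert abs(np.mean(tl) - expect) < 3 * se

    def test_three_leaf_topologies_exchangeable(self, rng):
        """The odd leaf out is uniform over the three choices."""
        from scipy.stats import chisquare
        counts = np.zeros(3)
        for _ in range(3000):
            t = simulate_genealogy(3, rng)
            first_pair = [i for i in range(3) if t.parent[i] == 3]
            odd = 3 - sum(first_pair)
            counts[odd] += 1
        assert chisquare(counts).pvalue > 0.001

    def test_leaves_below_partition(self, rng):
        t = simulate_genealogy(30, rng)
        lb = t.leaves_below()
        assert lb[2 * 30 - 2] == 30
        assert (lb[:30] == 1).all()


class TestMutations:
    def test_zero_theta_is_monomorphic(self, rng):
        t = simulate_genealogy(20, rng)
        assert np.unique(smm_locus(t, 0.0, rng)).size == 1

    def test_watterson_expected_segregating_sites(self, rng):
        n, theta = 50, 1.0
        S = [infinite_sites_counts(simulate_genealogy(n, rng), theta, rng).size
             for _ in range(4000)]
        expect = theta * harmonic(n - 1)
        se = np.std(S, ddof=1) / np.sqrt(len(S))
        assert abs(np.mean(S) - expect) < 3 * se

    def test_smm_heterozygosity_matches_closed_form(self, rng):
        """Mean sample He under coalescent SMM equals 1 - 1/sqrt(1+2*theta)."""
        theta = 1.0
        hes = [sumstats.expected_heterozygosity(
                   smm_locus(simulate_genealogy(100, rng), theta, rng))
               for _ in range(4000)]
        expect = 1 - 1 / np.sqrt(1 + 2 * theta)
        se = np.std(hes, ddof=1) / np.sqrt(len(hes))
        assert abs(np.mean(hes) - expect) < 3 * se

    def test_pi_equals_watterson_estimate_in_expectation(self, rng):
        """The D ~ 0 null: mean pi matches mean S/a1 under neutrality."""
        n, theta = 50, 2.0
        a1 = harmonic(n - 1)
        diffs = []
        for _ in range(4000):
            t = simulate_genealogy(n, rng)
            counts = infinite_sites_counts(t, theta, rng)
            pi = np.sum(counts * (n - counts)) / (n * (n - 1) / 2)
            diffs.append(pi - counts.size / a1)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se

    def test_constrained_walk_respects_window(self, rng):
        t = simulate_genealogy(40, rng)
        a = smm_locus(t, 20.0, rng, window=(13, 17))
        assert a.min() >= 13 and a.max() <= 17


class TestNullM:
    def test_degenerate_theta_gives_all_ones(self, rng):
        null = null_M_distribution(1e-9, 20, 5, rng, n_sims=20)
        assert (null == 1.0).all()

    def test_single_sim(self, rng):
        assert null_M_distribution(1.0, 20, 5, rng, n_sims=1).size == 1

    def test_distribution_concentrated_below_one(self, rng):
        null = null_M_distribution(1.0, 100, 15, rng, n_sims=200)
        q5 = np.sort(null)[9]
        assert 0.6 < q5 < 1.0


class TestHeq:
    def test_monomorphic_shortcut(self, rng):
        assert estimate_Heq(100, 1, rng) == 0.0

    def test_two_allele_bound(self, rng):
        v = estimate_Heq(100, 2, rng, min_accepted=200)
        assert 0.0 < v < 0.55

    def test_monotone_in_allele_count(self, rng):
        vals = [estimate_Heq(100, k, rng, min_accepted=200)
                for k in (2, 3, 4, 5)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_invalid_k_raises(self, rng):
        with pytest.raises(ValueError):
            estimate_Heq(10, 11, rng)

    def test_seed_stability(self):
        """Estimates from independent streams agree closely."""
        a = estimate_Heq(100, 4, np.random.default_rng(1), min_accepted=2000)
        b = estimate_Heq(100, 4, np.random.default_rng(2), min_accepted=2000)
        assert abs(a - b) < 0.01

    def test_cache_is_call_order_independent(self):
        c1, c2 = NullCache(9), NullCache(9)
        x1 = c1.heq(100, 3, min_accepted=200)
        c2.heq(100, 2, min_accepted=200)
        x2 = c2.heq(100, 3, min_accepted=200)
        assert x1 == x2


class TestTajimaNull:
    def test_requires_segregation(self, rng):
        with pytest.raises(ValueError):
            tajima_null_distribution(0, 50, rng)

    def test_singleton_conditioned_null_is_mostly_negative(self, rng):
        """With S=1 the site-frequency spectrum ~1/i makes singletons (and
        negative D) the norm."""
        null = tajima_null_distribution(1, 100, rng, n_sims=500)
        assert np.mean(null < 0) > 0.5
        assert null.max() <= 2.0  # bounded by the 50/50 configuration


class TestAgainstMsprime:
    def test_tree_length_distribution_matches_msprime(self, rng):
        """Independent implementation check of the genealogy simulator."""
        msprime = pytest.importorskip("msprime")
        n = 10
        ours = [simulate_genealogy(n, rng).total_length for _ in range(2000)]
        other = []
        # haploid samples with N=1 put msprime on the same time scale
        # (pairwise coalescence rate 1) as our simulator
        for ts in msprime.sim_ancestry(samples=n, ploidy=1,
                                       population_size=1,
                                       num_replicates=2000, random_seed=7):
            other.append(ts.first().total_branch_length)
        se = np.sqrt(np.var(ours) / 2000 + np.var(other) / 2000)
        assert abs(np.mean(ours) - np.mean(other)) < 3 * se
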