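"""Forward simulator: reproduction scheme, mutation, burn-in, sampling."""

import numpy as np
import pytest
from scipy import stats as sps

from sweepstakes import forward, sumstats
from sweepstakes.forward import (advance_generation, initialize_population,
                                 run_to_equilibrium, sample_cohort,
                                 sample_individuals, simulate_replicate)
from sweepstakes.offspring import (DemographyConfig, offspring_model_for,
                                   poisson_model)


def small_config(**kw):
    defaults = dict(effective_size=30, variance=2, n_loci=5,
                    mutation_rate=5e-4, sample_size=10)
    defaults.update(kw)
    return DemographyConfig(**defaults)


class TestMatingScheme:
    def test_census_constant_across_generations(self, rng):
        cfg = small_config(variance=40)
        model = offspring_model_for(40)
        pop = initialize_population(cfg, rng)
        for _ in range(5):
            pop = advance_generation(pop, model, rng)
            assert pop.census == cfg.census_size

    def test_poisson_reproduction_gives_poisson_offspring_counts(self, rng):
        """Per-parent offspring counts under V_k=2 pass a chi-square GOF
        against Poisson(2) on 1e5 parents."""
        nc = 100_000
        pa, ma = forward._draw_parents(nc, poisson_model(), rng)
        counts = np.bincount(np.concatenate([pa, ma]), minlength=nc)
        kmax = 9
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pmf = sps.poisson.pmf(np.arange(kmax), 2)
        probs = np.append(pmf, 1 - pmf.sum())
        stat, p = sps.chisquare(obs, nc * probs)
        assert p > 0.001

    def test_high_variance_concentrates_parentage(self, rng):
        """V_k=2000 leaves far fewer distinct parents than offspring."""
        nc = 2000
        pa, ma = forward._draw_parents(nc, offspring_model_for(2000), rng)
        distinct = np.unique(np.concatenate([pa, ma])).size
        assert distinct < 0.5 * nc


class TestMutation:
    def test_no_mutation_keeps_monomorphic(self, rng):
        cfg = small_config(mutation_rate=0.0)
        pop = initialize_population(cfg, rng, init="dirichlet",
                                    n_init_alleles=1)
        nxt = advance_generation(pop, poisson_model(), rng, mu=0.0)
        assert np.unique(nxt.microsat_genotypes).size == 1

    def test_constrained_alleles_stay_in_window(self, rng):
        cfg = small_config(marker_type="microsat_constrained",
                           mutation_rate=0.05)
        model = poisson_model()
        pop = initialize_population(cfg, rng)
        for _ in range(30):
            pop = advance_generation(pop, model, rng)
        g = pop.microsat_genotypes
        lo = forward.REFERENCE_REPEAT - forward.CONSTRAINED_STATES // 2
        assert g.min() >= lo
        assert g.max() <= lo + forward.CONSTRAINED_STATES - 1

    def test_reflection_bounces_off_walls(self):
        folded = forward._fold_into_window(np.arange(5, 26), 13, 17)
        assert folded.min() >= 13 and folded.max() <= 17

    def test_drift_only_heterozygosity_decays(self):
        """With mu=0, He is non-increasing in expectation under pure drift."""
        cfg = small_config(effective_size=10, n_loci=3, mutation_rate=0.0,
                           sample_size=5)
        drops = 0
        for rep in range(60):
            rng = np.random.default_rng(900 + rep)
            pop = initialize_population(cfg, rng, init="dirichlet",
                                        dirichlet_conc=1.0)
            he0 = sumstats.microsat_summary(pop.microsat_genotypes).het_expected
            pop, _ = run_to_equilibrium(cfg, poisson_model(), rng,
                                        burnin_generations=40, pop=pop)
            he1 = sumstats.microsat_summary(pop.microsat_genotypes).het_expected
            drops += he1 <= he0
        assert drops >= 0.95 * 60 - 5  # allow a few upward fluctuations


class TestInitialization:
    def test_single_allele_dirichlet_is_monomorphic(self, rng):
        pop = initialize_population(small_config(), rng, init="dirichlet",
                                    n_init_alleles=1)
        s = sumstats.microsat_summary(pop.microsat_genotypes)
        assert s.het_expected == 0.0

    def test_dirichlet_allele_count_bounded(self, rng):
        pop = initialize_population(small_config(), rng, init="dirichlet",
                                    dirichlet_conc=1.0, n_init_alleles=10)
        assert sumstats.microsat_summary(pop.microsat_genotypes).n_alleles <= 10

    def test_identical_streams_give_identical_populations(self):
        cfg = small_config()
        a = initialize_population(cfg, np.random.default_rng(5))
        b = initialize_population(cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(a.microsat_genotypes,
                                      b.microsat_genotypes)

    def test_coalescent_init_tracks_theta(self):
        """Founding heterozygosity scales with theta (equilibrium start)."""
        hes = []
        for mu in (5e-5, 5e-3):
            cfg = DemographyConfig(effective_size=100, variance=2, n_loci=30,
                                   mutation_rate=mu, sample_size=10)
            pop = initialize_population(cfg, np.random.default_rng(3))
            hes.append(sumstats.microsat_summary(pop.microsat_genotypes)
                       .het_expected)
        assert hes[0] < 0.2 < hes[1]


class TestBurnin:
    def test_zero_burnin_returns_initial_population(self):
        cfg = small_config()
        rng = np.random.default_rng(11)
        pop0 = initialize_population(cfg, np.random.default_rng(7))
        pop, diag = run_to_equilibrium(cfg, poisson_model(), rng,
                                       burnin_generations=0, pop=pop0)
        np.testing.assert_array_equal(pop.microsat_genotypes,
                                      pop0.microsat_genotypes)

    def test_diagnostics_trajectory_recorded(self, rng):
        cfg = small_config()
        _, diag = run_to_equilibrium(cfg, poisson_model(), rng,
                                     burnin_generations=60, check_interval=20)
        assert diag.generations[0] == 0
        assert diag.generations[-1] == 60
        assert len(diag.het_expected) == len(diag.generations)


class TestSampling:
    def test_oversampling_raises(self, rng):
        cfg = small_config()
        pop = initialize_population(cfg, rng)
        with pytest.raises(ValueError):
            sample_individuals(pop, cfg.census_size + 1, rng)

    def test_whole_population_sample(self, rng):
        cfg = small_config()
        pop = initialize_population(cfg, rng)
        ds = sample_individuals(pop, cfg.census_size, rng)
        assert ds.genotypes.shape[0] == cfg.census_size

    def test_sampling_is_deterministic_given_stream(self):
        cfg = small_config()
        pop = initialize_population(cfg, np.random.default_rng(1))
        a = sample_individuals(pop, 10, np.random.default_rng(2))
        b = sample_individuals(pop, 10, np.random.default_rng(2))
        np.testing.assert_array_equal(a.genotypes, b.genotypes)

    def test_cohort_sample_is_array_head(self, rng):
        cfg = small_config()
        pop = initialize_population(cfg, rng)
        ds = sample_cohort(pop, 10, rng)
        np.testing.assert_array_equal(ds.genotypes,
                                      pop.microsat_genotypes[:10])

    def test_replicate_determinism_end_to_end(self):
        cfg = small_config()
        model = poisson_model()
        a, _ = simulate_replicate(cfg, model, seed=42)
        b, _ = simulate_replicate(cfg, model, seed=42)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)


class TestSequenceMode:
    def seq_config(self, ne=50):
        return DemographyConfig(effective_size=ne, variance=2, n_loci=1,
                                mutation_rate=1e-5, sample_size=20,
                                marker_type="sequence")

    def test_replicate_produces_binary_matrix(self):
        cfg = self.seq_config()
        ds, _ = simulate_replicate(cfg, poisson_model(), seed=8)
        assert ds.genotypes.shape[0] == 2 * cfg.sample_size
        assert set(np.unique(ds.genotypes)) <= {0, 1}

    def test_segregating_sites_scale_with_theta(self):
        """Sample S tracks the Watterson expectation theta * a1."""
        cfg = self.seq_config()
        theta = 4 * cfg.effective_size * cfg.mutation_rate * 500
        n = 2 * cfg.sample_size
        a1 = np.sum(1.0 / np.arange(1, n))
        S = [simulate_replicate(cfg, poisson_model(), seed=100 + r,
                                sampling="uniform")[0].genotypes.shape[1]
             for r in range(40)]
        se = np.std(S, ddof=1) / np.sqrt(len(S))
        assert abs(np.mean(S) - theta * a1) < max(4 * se, 0.5)

    def test_monomorphic_start_has_no_variation(self):
        cfg = self.seq_config()
        rng = np.random.default_rng(0)
        pop = initialize_population(cfg, rng, init="dirichlet")
        ds = sample_individuals(pop, 20, rng)
        assert ds.genotypes.shape[1] == 0
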