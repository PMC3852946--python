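"""Individual-based forward-in-time simulation of a stable diploid population.

Each generation the N_c parents are shuffled into N_c/2 disjoint pairs; each
pair draws a family size from the configured offspring model (Poisson(2) or a
calibrated floored gamma); families accumulate until N_c offspring exist, the
last family being truncated so the census stays exactly constant.  If a full
pass of pairs falls short, parents are reshuffled and pairing continues.
Because each pair produces one family, the per-parent offspring variance
equals the family-size variance V_k, which is what the N_e/N_c = 4/(V_k+2)
mapping assumes.

Markers:

* ``microsat`` — repeat counts under a strict stepwise mutation model (SMM):
  each gene copy mutates at rate mu per generation by +-1 repeat.
* ``microsat_constrained`` — SMM reflected inside a 5-state window of
  adjacent repeat sizes (EST-like loci with restricted allelic range).
* ``sequence`` — one 500-bp locus under the infinite-sites model, per-site
  rate mu.  Mutations are tracked as abstract sites (each mutation is a new
  site by construction); a sampled dataset maps its segregating mutations to
  concrete positions.

Populations are initialized at approximate mutation-drift equilibrium: each
locus's founding allele frequencies are rendered by a Kingman-coalescent
sample at the configured theta (see :func:`initialize_population`), so the
study-scale burn-in of N_e generations under the actual offspring model
suffices; convergence is verified by the recorded K/He/F_is trajectory.
A symmetric-Dirichlet initialization is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .offspring import DemographyConfig, OffspringModel, draw_family_sizes
from . import sumstats

__all__ = [
    "Population",
    "SampleDataset",
    "BurninDiagnostics",
    "initialize_population",
    "advance_generation",
    "run_to_equilibrium",
    "sample_individuals",
    "simulate_replicate",
    "default_burnin",
]

#: reference repeat count around which microsatellite alleles are initialized
REFERENCE_REPEAT = 15

#: width of the allele window for constrained (EST-like) microsatellites
CONSTRAINED_STATES = 5

#: length of the simulated DNA fragment, in base pairs
SEQUENCE_LENGTH = 500


@dataclass
class Population:
    """Genotypic state of one generation.

    ``microsat_genotypes`` has shape (N_c, L, 2) and holds repeat counts.
    In sequence mode ``seq_haplotypes`` (N_c, 2) holds abstract haplotype
    ids indexing ``mutation_parent``/the mutation registry: haplotype 0 is
    the ancestral sequence and haplotype h>0 carries the mutations on the
    chain h -> mutation_parent[h] -> ... -> 0, each a unique site.
    """

    config: DemographyConfig
    microsat_genotypes: np.ndarray | None = None
    seq_haplotypes: np.ndarray | None = None
    mutation_parent: list[int] = field(default_factory=lambda: [0])
    generation_index: int = 0

    @property
    def census(self) -> int:
        if self.microsat_genotypes is not None:
            return self.microsat_genotypes.shape[0]
        return self.seq_haplotypes.shape[0]


@dataclass(frozen=True)
class SampleDataset:
    """Genotypes of n sampled individuals; the unit consumed by every test.

    ``genotypes``: (n, L, 2) repeat counts for microsatellite markers, or a
    (2n, n_sites) 0/1 haplotype matrix for sequences (n_sites = segregating
    sites in the sample; monomorphic samples have 0 columns).
    """

    genotypes: np.ndarray
    marker_type: str
    effective_size: int
    variance: float
    seed: int
    replicate_id: int
    sequence_length: int = SEQUENCE_LENGTH


@dataclass
class BurninDiagnostics:
    """K/He/F_is trajectory recorded during burn-in, plus a convergence flag.

    Convergence: least-squares slope of the second half of the He
    trajectory below ``slope_threshold`` in absolute value (per generation).
    """

    generations: np.ndarray
    n_alleles: np.ndarray
    het_expected: np.ndarray
    f_is: np.ndarray
    converged: bool
    he_slope: float


def default_burnin(config: DemographyConfig) -> int:
    """Burn-in length: N_e generations (populations start near equilibrium)."""
    return config.effective_size


#: gene copies in the coalescent founder sample used to seed a population
FOUNDER_COPIES = 200


def _init_microsat_coalescent(
    config: DemographyConfig, rng: np.random.Generator
) -> np.ndarray:
    """Founding genotypes drawn from the stationary SMM distribution.

    Per locus a Kingman-coalescent SMM sample of min(200, 2 N_c) gene copies
    at theta = 4 N_e mu renders the equilibrium allele-frequency cloud
    (including its rare-allele scatter); every population gene copy is then
    an i.i.d. draw from that founder pool.
    """
    from . import coalescent  # deferred: avoids import-order clutter

    nc = config.census_size
    n_founders = min(FOUNDER_COPIES, 2 * nc)
    constrained = config.marker_type == "microsat_constrained"
    geno = np.empty((nc, config.n_loci, 2), dtype=np.int16)
    for locus in range(config.n_loci):
        tree = coalescent.simulate_genealogy(n_founders, rng)
        alleles = coalescent.smm_locus(tree, config.theta, rng)
        alleles = alleles + REFERENCE_REPEAT
        if constrained:
            # fold the free-walk cloud into the window by reflection, the
            # state the bounded walk reaches after the cloud is squeezed
            lo = REFERENCE_REPEAT - CONSTRAINED_STATES // 2
            alleles = _fold_into_window(alleles, lo,
                                        lo + CONSTRAINED_STATES - 1)
        picks = rng.integers(0, n_founders, size=(nc, 2))
        geno[:, locus, :] = alleles[picks]
    return geno


def _fold_into_window(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Reflect integers into [lo, hi] (billiard/fold map, period 2(hi-lo))."""
    width = hi - lo
    if width == 0:
        return np.full_like(x, lo)
    y = np.mod(x - lo, 2 * width)
    y = np.where(y > width, 2 * width - y, y)
    return y + lo


def _init_sequence_coalescent(
    config: DemographyConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """Founding haplotypes from an infinite-sites coalescent sample.

    The founder genealogy's mutations become the initial entries of the
    mutation registry; each founder leaf's registry chain mirrors its
    root-to-leaf path, and population gene copies draw founder haplotypes
    i.i.d.
    """
    from . import coalescent

    nc = config.census_size
    n_founders = min(FOUNDER_COPIES, 2 * nc)
    theta = 4.0 * config.effective_size * config.mutation_rate * SEQUENCE_LENGTH
    tree = coalescent.simulate_genealogy(n_founders, rng)
    branches = coalescent._mutation_branches(tree, theta, rng)
    per_branch = np.bincount(branches, minlength=2 * n_founders - 1)
    parents = [0]
    chain_head = np.zeros(2 * n_founders - 1, dtype=np.int64)
    for node in range(2 * n_founders - 3, -1, -1):
        head = chain_head[tree.parent[node]]
        for _ in range(per_branch[node]):
            parents.append(int(head))
            head = len(parents) - 1
        chain_head[node] = head
    founder_haps = chain_head[:n_founders]
    picks = rng.integers(0, n_founders, size=(nc, 2))
    return founder_haps[picks], parents


def initialize_population(
    config: DemographyConfig,
    rng: np.random.Generator,
    init: str = "coalescent",
    dirichlet_conc: float | None = None,
    n_init_alleles: int | None = None,
) -> Population:
    """Draw the founding generation.

    ``init="coalescent"`` (default): allele frequencies per locus are drawn
    from the model's stationary distribution, rendered by a coalescent
    sample at the configured theta, so the study-scale burn-in of N_e
    generations starts from (approximate) mutation-drift equilibrium.

    ``init="dirichlet"``: frequencies over ``n_init_alleles`` adjacent
    repeat states from a symmetric Dirichlet (concentration theta/K by
    default); sequences start monomorphic.
    """
    nc = config.census_size
    if init == "coalescent":
        if config.marker_type == "sequence":
            haps, parents = _init_sequence_coalescent(config, rng)
            return Population(config=config, seq_haplotypes=haps,
                              mutation_parent=parents)
        return Population(
            config=config,
            microsat_genotypes=_init_microsat_coalescent(config, rng),
        )
    if init != "dirichlet":
        raise ValueError(f"unknown init mode {init!r}")

    if config.marker_type == "sequence":
        return Population(
            config=config,
            seq_haplotypes=np.zeros((nc, 2), dtype=np.int64),
        )
    if n_init_alleles is None:
        n_init_alleles = (CONSTRAINED_STATES
                          if config.marker_type == "microsat_constrained"
                          else 10)
    if dirichlet_conc is None:
        dirichlet_conc = max(config.theta / n_init_alleles, 1e-3)

    lo = REFERENCE_REPEAT - n_init_alleles // 2
    states = lo + np.arange(n_init_alleles)
    geno = np.empty((nc, config.n_loci, 2), dtype=np.int16)
    for locus in range(config.n_loci):
        if n_init_alleles == 1:
            geno[:, locus, :] = states[0]
        else:
            freqs = rng.dirichlet(np.full(n_init_alleles, dirichlet_conc))
            geno[:, locus, :] = rng.choice(states, size=(nc, 2), p=freqs)
    return Population(config=config, microsat_genotypes=geno)


def _draw_parents(
    nc: int, model: OffspringModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Offspring -> (father, mother) index arrays under monogamous pairing."""
    fams, fathers, mothers = [], [], []
    total = 0
    while total < nc:
        perm = rng.permutation(nc)
        pairs = perm.reshape(-1, 2)
        sizes = draw_family_sizes(model, pairs.shape[0], rng)
        fams.append(sizes)
        fathers.append(pairs[:, 0])
        mothers.append(pairs[:, 1])
        total += int(sizes.sum())
    sizes = np.concatenate(fams)
    fathers = np.concatenate(fathers)
    mothers = np.concatenate(mothers)
    child_fam = np.repeat(np.arange(sizes.size), sizes)[:nc]
    return fathers[child_fam], mothers[child_fam]


def advance_generation(
    pop: Population,
    model: OffspringModel,
    rng: np.random.Generator,
    mu: float | None = None,
) -> Population:
    """Produce the next generation: mating, Mendelian transmission, mutation."""
    config = pop.config
    nc = config.census_size
    if pop.census < 2:
        raise ValueError("population must have at least 2 individuals")
    if mu is None:
        mu = config.mutation_rate

    pa, ma = _draw_parents(nc, model, rng)

    if config.marker_type == "sequence":
        bits = rng.integers(0, 2, size=(2, nc), dtype=np.int64)
        hap = np.empty((nc, 2), dtype=np.int64)
        src = pop.seq_haplotypes
        hap[:, 0] = src[pa, bits[0]]
        hap[:, 1] = src[ma, bits[1]]
        parents = pop.mutation_parent
        n_mut = rng.binomial(2 * nc, mu * SEQUENCE_LENGTH)
        if n_mut:
            parents = list(parents)
            flat = rng.integers(0, 2 * nc, size=n_mut)
            flat_view = hap.reshape(-1)
            for f in flat:
                new_id = len(parents)
                parents.append(int(flat_view[f]))
                flat_view[f] = new_id
        return Population(
            config=config,
            seq_haplotypes=hap,
            mutation_parent=parents,
            generation_index=pop.generation_index + 1,
        )

    L = config.n_loci
    lr = np.arange(L)
    bits = rng.integers(0, 2, size=(2, nc, L), dtype=np.int8)
    geno = np.empty((nc, L, 2), dtype=np.int16)
    src = pop.microsat_genotypes
    geno[:, :, 0] = src[pa[:, None], lr[None, :], bits[0]]
    geno[:, :, 1] = src[ma[:, None], lr[None, :], bits[1]]

    # sparse SMM mutation: expected nc*L*2*mu events per generation
    n_mut = rng.binomial(nc * L * 2, mu)
    if n_mut:
        flat = rng.integers(0, nc * L * 2, size=n_mut)
        steps = rng.choice(np.array([-1, 1], dtype=np.int16), size=n_mut)
        view = geno.reshape(-1)
        if config.marker_type == "microsat_constrained":
            lo = REFERENCE_REPEAT - CONSTRAINED_STATES // 2
            hi = lo + CONSTRAINED_STATES - 1
            prop = view[flat].astype(np.int64) + steps
            prop = np.where(prop > hi, hi - 1, prop)   # reflect at the walls
            prop = np.where(prop < lo, lo + 1, prop)
            view[flat] = prop.astype(np.int16)
        else:
            view[flat] += steps
    return Population(
        config=config,
        microsat_genotypes=geno,
        generation_index=pop.generation_index + 1,
    )


def run_to_equilibrium(
    config: DemographyConfig,
    model: OffspringModel,
    rng: np.random.Generator,
    burnin_generations: int | None = None,
    check_interval: int = 50,
    slope_threshold: float = 5e-4,
    pop: Population | None = None,
) -> tuple[Population, BurninDiagnostics]:
    """Advance ``burnin_generations`` and record the K/He/F_is trajectory.

    Non-convergence is reported through the diagnostics, never fatal: the
    fixed study-scale burn-in is part of the study design.
    """
    if burnin_generations is None:
        burnin_generations = default_burnin(config)
    if pop is None:
        pop = initialize_population(config, rng)

    gens, ks, hes, fiss = [], [], [], []

    def record(p: Population) -> None:
        gens.append(p.generation_index)
        if p.microsat_genotypes is not None:
            stats = sumstats.microsat_summary(p.microsat_genotypes)
            ks.append(stats.n_alleles)
            hes.append(stats.het_expected)
            fiss.append(stats.f_is if stats.f_is is not None else np.nan)
        else:
            k = len(set(p.seq_haplotypes.reshape(-1).tolist()))
            ks.append(float(k))
            hes.append(np.nan)
            fiss.append(np.nan)

    record(pop)
    for g in range(1, burnin_generations + 1):
        pop = advance_generation(pop, model, rng)
        if g % check_interval == 0 or g == burnin_generations:
            record(pop)

    gens_a = np.asarray(gens, dtype=float)
    hes_a = np.asarray(hes, dtype=float)
    slope = np.nan
    converged = True
    if hes_a.size >= 4 and np.isfinite(hes_a).all():
        half = hes_a.size // 2
        x, y = gens_a[half:], hes_a[half:]
        slope = float(np.polyfit(x, y, 1)[0])
        converged = abs(slope) < slope_threshold
    diag = BurninDiagnostics(
        generations=gens_a,
        n_alleles=np.asarray(ks, dtype=float),
        het_expected=hes_a,
        f_is=np.asarray(fiss, dtype=float),
        converged=converged,
        he_slope=slope,
    )
    return pop, diag


def _sequence_sample_matrix(
    pop: Population, idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """0/1 site matrix (2n x S) for the sampled gene copies.

    Walks each sampled haplotype's mutation chain; mutations segregating in
    the sample become columns (mutations carried by all or no sampled copies
    drop out, as they would from real alignments).
    """
    hap_ids = pop.seq_haplotypes[idx].reshape(-1)
    chains = []
    for h in hap_ids:
        muts = set()
        node = int(h)
        while node != 0:
            muts.add(node)
            node = pop.mutation_parent[node]
        chains.append(muts)
    n_copies = len(chains)
    counts: dict[int, int] = {}
    for muts in chains:
        for m in muts:
            counts[m] = counts.get(m, 0) + 1
    seg = sorted(m for m, c in counts.items() if 0 < c < n_copies)
    if len(seg) > SEQUENCE_LENGTH:
        raise RuntimeError(
            f"sample segregates at {len(seg)} sites; exceeds the "
            f"{SEQUENCE_LENGTH}-bp fragment (infinite-sites violation)"
        )
    mat = np.zeros((n_copies, len(seg)), dtype=np.int8)
    col = {m: j for j, m in enumerate(seg)}
    for i, muts in enumerate(chains):
        for m in muts:
            j = col.get(m)
            if j is not None:
                mat[i, j] = 1
    return mat


def sample_individuals(
    pop: Population,
    n: int,
    rng: np.random.Generator,
    seed: int = 0,
    replicate_id: int = 0,
) -> SampleDataset:
    """Uniform sample of n individuals without replacement."""
    nc = pop.census
    if n > nc:
        raise ValueError(f"cannot sample {n} individuals from census {nc}")
    idx = rng.choice(nc, size=n, replace=False)
    return _dataset_from_indices(pop, idx, rng, seed, replicate_id)


def sample_cohort(
    pop: Population,
    n: int,
    rng: np.random.Generator,
    seed: int = 0,
    replicate_id: int = 0,
) -> SampleDataset:
    """Sample n individuals as a local cohort of whole sibships.

    Offspring arrays are filled family-by-family in random family order, so
    the first n individuals are complete broods until n is reached.  This
    emulates field sampling of a cohort in high-fecundity species, where a
    handful of families can dominate the catch; with Poisson reproduction
    (families of ~2) it is practically indistinguishable from uniform
    sampling.
    """
    nc = pop.census
    if n > nc:
        raise ValueError(f"cannot sample {n} individuals from census {nc}")
    idx = np.arange(n)
    return _dataset_from_indices(pop, idx, rng, seed, replicate_id)


def _dataset_from_indices(pop, idx, rng, seed, replicate_id) -> SampleDataset:
    if pop.microsat_genotypes is not None:
        geno = pop.microsat_genotypes[idx].copy()
    else:
        geno = _sequence_sample_matrix(pop, idx, rng)
    return SampleDataset(
        genotypes=geno,
        marker_type=pop.config.marker_type,
        effective_size=pop.config.effective_size,
        variance=pop.config.variance,
        seed=seed,
        replicate_id=replicate_id,
    )


def simulate_replicate(
    config: DemographyConfig,
    model: OffspringModel,
    seed: int,
    replicate_id: int = 0,
    burnin_generations: int | None = None,
    sampling: str = "cohort",
) -> tuple[SampleDataset, BurninDiagnostics]:
    """One full replicate: initialize, burn in, sample ``config.sample_size``.

    ``sampling`` is ``"cohort"`` (the study condition; see
    :func:`sample_cohort`) or ``"uniform"``.
    """
    rng = np.random.default_rng(seed)
    pop, diag = run_to_equilibrium(
        config, model, rng, burnin_generations=burnin_generations
    )
    sampler = sample_cohort if sampling == "cohort" else sample_individuals
    ds = sampler(
        pop, config.sample_size, rng, seed=seed, replicate_id=replicate_id
    )
    return ds, diag
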