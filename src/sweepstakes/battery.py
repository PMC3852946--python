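"""The four bottleneck-detection procedures.

Each test consumes a :class:`~sweepstakes.forward.SampleDataset` (or the raw
genotype array) and returns a :class:`TestResult` with the decision, the
statistic it is based on, and a p-value where one exists.  All tests are
one-sided in the direction a bottleneck would push the statistic:

* ``m_ratio_ft``   — dataset-mean M-ratio below the fixed 0.68 rule of thumb.
* ``m_ratio_sim``  — mean M below the empirical 5% quantile of a null built
  from 1000 Kingman-coalescent SMM datasets at the true theta = 4 N_e mu.
* ``het_excess``   — one-tailed Wilcoxon signed-rank of per-locus He against
  the simulated equilibrium heterozygosity given the observed allele count.
* ``tajima``       — observed D against 1000 constant-size infinite-sites
  coalescent simulations at theta estimated by pi (positive D signals
  decline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import coalescent, sumstats
from .forward import (CONSTRAINED_STATES, REFERENCE_REPEAT, SampleDataset)

__all__ = [
    "TestResult",
    "TestBatteryResult",
    "M_RATIO_THRESHOLD",
    "m_ratio_ft_test",
    "m_ratio_sim_test",
    "het_excess_test",
    "tajima_test",
    "run_battery",
]

#: the conservation-genetics "rule of thumb" critical M-ratio
M_RATIO_THRESHOLD = 0.68


@dataclass(frozen=True)
class TestResult:
    name: str
    call: bool
    statistic: float | None
    p_value: float | None = None
    critical_value: float | None = None
    applicable: bool = True
    note: str = ""


@dataclass(frozen=True)
class TestBatteryResult:
    alpha: float
    m_ratio_ft: TestResult | None = None
    m_ratio_sim: TestResult | None = None
    het_excess: TestResult | None = None
    tajima: TestResult | None = None


def _genotypes(dataset: SampleDataset | np.ndarray) -> np.ndarray:
    if isinstance(dataset, SampleDataset):
        return dataset.genotypes
    return np.asarray(dataset)


def m_ratio_ft_test(dataset: SampleDataset | np.ndarray) -> TestResult:
    """Fixed-threshold M-ratio test: bottleneck iff mean M < 0.68 (strict)."""
    m = sumstats.m_ratio(_genotypes(dataset))
    return TestResult(name="m_ratio_ft", call=m < M_RATIO_THRESHOLD,
                      statistic=m, critical_value=M_RATIO_THRESHOLD)


def m_ratio_sim_test(
    dataset: SampleDataset | np.ndarray,
    true_ne: float,
    true_mu: float,
    cache: coalescent.NullCache,
    n_sims: int = 1000,
    alpha: float = 0.05,
) -> TestResult:
    """Simulated-critical-value M-ratio test.

    The null distribution of the dataset-mean M is rebuilt from ``n_sims``
    coalescent SMM datasets with the same locus and sample numbers, at
    theta = 4 * true_ne * true_mu (the generating values, as an informed
    empiricist would supply).  The critical value is the empirical
    alpha-quantile taken as a lower-tail order statistic without
    interpolation; the call requires the observed mean M strictly below it.
    """
    geno = _genotypes(dataset)
    n_genes = geno.shape[0] * 2
    theta = 4.0 * true_ne * true_mu
    null = cache.null_m(theta, n_genes, geno.shape[1], n_sims=n_sims)
    order = max(int(np.floor(alpha * null.size)) - 1, 0)
    crit = float(np.sort(null)[order])
    m = sumstats.m_ratio(geno)
    p = float(np.mean(null <= m))
    return TestResult(name="m_ratio_sim", call=m < crit, statistic=m,
                      p_value=p, critical_value=crit)


def het_excess_test(
    dataset: SampleDataset | np.ndarray,
    cache: coalescent.NullCache,
    alpha: float = 0.05,
    min_polymorphic: int = 4,
    window: tuple[int, int] | None = None,
) -> TestResult:
    """Heterozygosity-excess test (Wilcoxon signed-rank, one-tailed).

    Per polymorphic locus the observed unbiased He is compared with the
    simulated equilibrium heterozygosity expected for its allele count;
    systematic positive differences across loci signal a bottleneck.  For
    size-constrained loci the conditional-heterozygosity null uses the same
    reflected mutation window as the data (the analyst knows the marker
    class), keeping the test calibrated at V_k = 2.
    """
    geno = _genotypes(dataset)
    if (window is None and isinstance(dataset, SampleDataset)
            and dataset.marker_type == "microsat_constrained"):
        lo = REFERENCE_REPEAT - CONSTRAINED_STATES // 2
        window = (lo, lo + CONSTRAINED_STATES - 1)
    n_genes = geno.shape[0] * 2
    deltas = []
    for l in range(geno.shape[1]):
        locus = geno[:, l, :]
        k = sumstats.allele_counts(locus)
        if k < 2:
            continue
        he = sumstats.expected_heterozygosity(locus)
        deltas.append(he - cache.heq(n_genes, k, window=window))
    if len(deltas) < min_polymorphic:
        return TestResult(name="het_excess", call=False, statistic=None,
                          applicable=False,
                          note=f"only {len(deltas)} polymorphic loci")
    deltas = np.asarray(deltas)
    if np.all(deltas == 0):
        p = 1.0
    else:
        # exact sign-rank for the locus counts used here (<= 25 informative
        # loci); the normal approximation only beyond that
        method = "exact" if deltas.size <= 25 else "approx"
        p = float(sps.wilcoxon(deltas, alternative="greater",
                               method=method).pvalue)
    return TestResult(name="het_excess", call=p < alpha,
                      statistic=float(np.mean(deltas)), p_value=p)


def tajima_test(
    dataset: SampleDataset | np.ndarray,
    rng: np.random.Generator,
    alpha: float = 0.05,
    n_sims: int = 1000,
) -> TestResult:
    """Tajima's D test, decline side (D significantly greater than 0).

    Significance by simulation: Hudson-style fixed-S coalescent replicates
    (exactly the observed number of segregating sites thrown on each
    simulated genealogy, same sample size); the one-tailed p-value is the
    fraction of replicates whose D is at least the observed D.
    """
    sites = _genotypes(dataset)
    S, pi, d = sumstats.tajimas_d(sites)
    if d is None:
        return TestResult(name="tajima", call=False, statistic=None,
                          applicable=False, note="S=0, D undefined")
    null = coalescent.tajima_null_distribution(S, sites.shape[0], rng,
                                               n_sims=n_sims)
    p = float(np.mean(null >= d))
    return TestResult(name="tajima", call=p < alpha, statistic=d, p_value=p)


def run_battery(
    dataset: SampleDataset,
    true_ne: float,
    true_mu: float,
    cache: coalescent.NullCache,
    rng: np.random.Generator,
    alpha: float = 0.05,
    n_sims: int = 1000,
) -> TestBatteryResult:
    """All tests applicable to the dataset's marker type."""
    if dataset.marker_type == "sequence":
        return TestBatteryResult(
            alpha=alpha,
            tajima=tajima_test(dataset, rng, alpha=alpha, n_sims=n_sims),
        )
    return TestBatteryResult(
        alpha=alpha,
        m_ratio_ft=m_ratio_ft_test(dataset),
        m_ratio_sim=m_ratio_sim_test(dataset, true_ne, true_mu, cache,
                                     n_sims=n_sims, alpha=alpha),
        het_excess=het_excess_test(dataset, cache, alpha=alpha),
    )
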