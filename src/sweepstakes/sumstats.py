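"""Per-dataset summary statistics: He, Ho, K, F_is, M-ratio, S, pi, Tajima's D.

Conventions:

* He is the unbiased Nei estimator ``n/(n-1) * (1 - sum p_i^2)`` over the
  ``n`` sampled gene copies.
* The M-ratio of a locus is the number of occupied repeat states divided by
  the inclusive range ``max - min + 1`` (Garza-Williamson); monomorphic loci
  carry M = 1 (a single state shows no gap).
* The multilocus F_is is a ratio of averages, ``1 - sum Ho / sum He`` over
  polymorphic loci, which is stable when polymorphism is low.
* Tajima's D is undefined at S = 0 and reported as None.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SummaryStats",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "allele_counts",
    "m_ratio_locus",
    "m_ratio",
    "f_is",
    "microsat_summary",
    "tajima_constants",
    "tajimas_d",
    "sequence_summary",
]


@dataclass
class SummaryStats:
    """Dataset-level summaries (means across loci where applicable)."""

    het_expected: float
    het_observed: float
    n_alleles: float
    f_is: float | None
    m_ratio: float | None
    pct_polymorphic: float
    per_locus_he: np.ndarray | None = None
    per_locus_k: np.ndarray | None = None
    # sequence-only
    seg_sites: int | None = None
    pi: float | None = None
    tajima_d: float | None = None


def _freqs(copies: np.ndarray) -> tuple[np.ndarray, int]:
    copies = np.asarray(copies).reshape(-1)
    _, counts = np.unique(copies, return_counts=True)
    return counts / copies.size, copies.size


def expected_heterozygosity(copies: np.ndarray) -> float:
    """Unbiased expected heterozygosity of one locus from its gene copies."""
    p, n = _freqs(copies)
    if n < 2:
        raise ValueError("need at least 2 gene copies")
    return float(n / (n - 1) * (1.0 - np.sum(p * p)))


def observed_heterozygosity(locus_genotypes: np.ndarray) -> float:
    """Fraction of heterozygous individuals at one locus; input (n, 2)."""
    g = np.asarray(locus_genotypes)
    return float(np.mean(g[:, 0] != g[:, 1]))


def allele_counts(copies: np.ndarray) -> int:
    return int(np.unique(np.asarray(copies).reshape(-1)).size)


def m_ratio_locus(copies: np.ndarray) -> float:
    """Occupied allelic states over the inclusive allele-size range."""
    alleles = np.unique(np.asarray(copies).reshape(-1))
    span = int(alleles.max() - alleles.min()) + 1
    return float(alleles.size / span)


def m_ratio(genotypes: np.ndarray) -> float:
    """Dataset M: mean of per-locus M-ratios; genotypes (n, L, 2)."""
    return float(np.mean([m_ratio_locus(genotypes[:, l, :])
                          for l in range(genotypes.shape[1])]))


def f_is(genotypes: np.ndarray) -> float | None:
    """Multilocus inbreeding coefficient 1 - sum(Ho)/sum(He), polymorphic loci.

    Returns None when every locus is monomorphic (undefined).
    """
    he_sum = ho_sum = 0.0
    informative = 0
    for l in range(genotypes.shape[1]):
        locus = genotypes[:, l, :]
        if allele_counts(locus) < 2:
            continue
        he_sum += expected_heterozygosity(locus)
        ho_sum += observed_heterozygosity(locus)
        informative += 1
    if informative == 0:
        return None
    return 1.0 - ho_sum / he_sum


def microsat_summary(genotypes: np.ndarray) -> SummaryStats:
    """All Table-style summaries for a (n, L, 2) microsatellite array."""
    L = genotypes.shape[1]
    he = np.array([expected_heterozygosity(genotypes[:, l, :]) for l in range(L)])
    ho = np.array([observed_heterozygosity(genotypes[:, l, :]) for l in range(L)])
    k = np.array([allele_counts(genotypes[:, l, :]) for l in range(L)])
    m = np.array([m_ratio_locus(genotypes[:, l, :]) for l in range(L)])
    return SummaryStats(
        het_expected=float(he.mean()),
        het_observed=float(ho.mean()),
        n_alleles=float(k.mean()),
        f_is=f_is(genotypes),
        m_ratio=float(m.mean()),
        pct_polymorphic=float(100.0 * np.mean(k >= 2)),
        per_locus_he=he,
        per_locus_k=k,
    )


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for a sample of n sequences."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def pairwise_diversity(sites: np.ndarray) -> float:
    """Mean pairwise difference pi from a (n, S) 0/1 haplotype matrix."""
    n = sites.shape[0]
    if sites.shape[1] == 0:
        return 0.0
    ones = sites.sum(axis=0).astype(float)
    return float(np.sum(ones * (n - ones)) / (n * (n - 1) / 2))


def tajimas_d(sites: np.ndarray) -> tuple[int, float, float | None]:
    """(S, pi, D) from a 0/1 haplotype matrix; D is None when S = 0."""
    n = sites.shape[0]
    # drop non-segregating columns defensively
    ones = sites.sum(axis=0)
    seg = (ones > 0) & (ones < n)
    sites = sites[:, seg]
    S = sites.shape[1]
    pi = pairwise_diversity(sites)
    if S == 0:
        return 0, 0.0, None
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    d = (pi - S / c["a1"]) / np.sqrt(var)
    return S, pi, float(d)


def sequence_summary(sites: np.ndarray) -> SummaryStats:
    """Summaries for a sequence dataset (2n x S matrix of 0/1 states)."""
    S, pi, d = tajimas_d(sites)
    n = sites.shape[0]
    he = 0.0
    if S:
        p = sites.sum(axis=0) / n
        he = float(np.mean(2 * p * (1 - p)) * n / (n - 1))
    return SummaryStats(
        het_expected=he,
        het_observed=np.nan,
        n_alleles=float(S + 1),
        f_is=None,
        m_ratio=None,
        pct_polymorphic=100.0 if S else 0.0,
        seg_sites=S,
        pi=pi,
        tajima_d=d,
    )
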