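"""Kingman coalescent null model (Wright-Fisher, V_k = 2 by construction).

Used to build the null distributions the bottleneck tests compare against:
the critical value of the simulated M-ratio test, the equilibrium
heterozygosity given an observed allele count (the quantity the
heterozygosity-excess test subtracts), and Tajima's D significance.

Trees are simulated in coalescent time units (2 N_e generations); mutations
fall on branches as a Poisson process of rate theta/2 per unit branch
length, so the only demographic coupling needed is theta = 4 N_e mu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import sumstats

__all__ = [
    "Genealogy",
    "simulate_genealogy",
    "smm_locus",
    "infinite_sites_counts",
    "infinite_sites_matrix",
    "null_M_distribution",
    "estimate_Heq",
    "tajima_null_distribution",
    "HeqEstimationError",
    "NullCache",
]


class HeqEstimationError(RuntimeError):
    """Raised when the conditional-heterozygosity simulation cannot accept
    enough loci with the requested allele count within its budget."""


@dataclass
class Genealogy:
    """Binary coalescent tree over ``n`` sampled gene copies.

    Nodes 0..n-1 are leaves; internal nodes are numbered in coalescence
    order, so every child has a smaller index than its parent and the root
    is node 2n-2.  ``branch_length[i]`` is the branch above node i (0 for
    the root); times are in units of 2N generations.
    """

    n: int
    parent: np.ndarray
    branch_length: np.ndarray

    @property
    def total_length(self) -> float:
        return float(self.branch_length.sum())

    def leaves_below(self) -> np.ndarray:
        counts = np.zeros(2 * self.n - 1, dtype=np.int64)
        counts[: self.n] = 1
        for i in range(2 * self.n - 2):
            counts[self.parent[i]] += counts[i]
        return counts


def simulate_genealogy(n_genes: int, rng: np.random.Generator) -> Genealogy:
    """Standard Kingman coalescent: Exp(k(k-1)/2) waiting times, uniform merges."""
    if n_genes < 2:
        raise ValueError("need at least 2 gene copies")
    n = n_genes
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    for nxt in range(n, n_nodes):
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        # replace the two merged lineages with the new node
        active[min(i, j)] = nxt
        active.pop(max(i, j))
    blen = np.zeros(n_nodes)
    has_parent = parent >= 0
    blen[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    return Genealogy(n=n, parent=parent, branch_length=blen)


def _mutation_branches(
    tree: Genealogy, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Branch index of each mutation; count ~ Poisson(total_length * theta/2)."""
    total = tree.total_length
    n_mut = rng.poisson(total * theta / 2.0)
    if n_mut == 0:
        return np.zeros(0, dtype=np.int64)
    cum = np.cumsum(tree.branch_length)
    return np.searchsorted(cum, rng.uniform(0.0, total, size=n_mut))


def smm_locus(
    tree: Genealogy,
    theta: float,
    rng: np.random.Generator,
    window: tuple[int, int] | None = None,
) -> np.ndarray:
    """Leaf allele states (repeat counts relative to the root) under strict SMM.

    With ``window=(lo, hi)`` the +-1 walk is reflected at the window walls
    (size-constrained loci); the root state is the window midpoint.
    """
    branches = _mutation_branches(tree, theta, rng)
    n_nodes = 2 * tree.n - 1
    if window is None:
        delta = np.zeros(n_nodes, dtype=np.int64)
        if branches.size:
            steps = rng.choice(np.array([-1, 1]), size=branches.size)
            np.add.at(delta, branches, steps)
        state = np.zeros(n_nodes, dtype=np.int64)
        for i in range(n_nodes - 2, -1, -1):
            state[i] = state[tree.parent[i]] + delta[i]
        return state[: tree.n]
    lo, hi = window
    per_branch: list[list[int]] = [[] for _ in range(n_nodes)]
    if branches.size:
        steps = rng.choice(np.array([-1, 1]), size=branches.size)
        for b, s in zip(branches, steps):
            per_branch[b].append(int(s))
    state = np.zeros(n_nodes, dtype=np.int64)
    state[n_nodes - 1] = (lo + hi) // 2
    for i in range(n_nodes - 2, -1, -1):
        x = state[tree.parent[i]]
        for s in per_branch[i]:
            x += s
            if x > hi:
                x = hi - 1
            elif x < lo:
                x = lo + 1
        state[i] = x
    return state[: tree.n]


def infinite_sites_counts(
    tree: Genealogy, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Derived-allele count of each segregating site under infinite sites."""
    branches = _mutation_branches(tree, theta, rng)
    if branches.size == 0:
        return np.zeros(0, dtype=np.int64)
    leaves = tree.leaves_below()
    counts = leaves[branches]
    return counts[(counts > 0) & (counts < tree.n)]


def infinite_sites_matrix(
    tree: Genealogy, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """(n x S) 0/1 haplotype matrix under infinite sites."""
    branches = _mutation_branches(tree, theta, rng)
    n = tree.n
    cols = []
    for b in branches:
        col = np.zeros(n, dtype=np.int8)
        _mark_descendants(tree, int(b), col)
        if 0 < col.sum() < n:
            cols.append(col)
    if not cols:
        return np.zeros((n, 0), dtype=np.int8)
    return np.stack(cols, axis=1)


def _mark_descendants(tree: Genealogy, node: int, out: np.ndarray) -> None:
    children: dict[int, list[int]] = {}
    for i, p in enumerate(tree.parent):
        if p >= 0:
            children.setdefault(int(p), []).append(i)
    stack = [node]
    while stack:
        v = stack.pop()
        if v < tree.n:
            out[v] = 1
        else:
            stack.extend(children.get(v, []))


def _pi_from_counts(counts: np.ndarray, n: int) -> float:
    if counts.size == 0:
        return 0.0
    return float(np.sum(counts * (n - counts)) / (n * (n - 1) / 2))


def null_M_distribution(
    theta: float,
    n_genes: int,
    n_loci: int,
    rng: np.random.Generator,
    n_sims: int = 1000,
) -> np.ndarray:
    """Empirical null of the dataset-mean M-ratio under Wright-Fisher SMM.

    Each of the ``n_sims`` datasets is ``n_loci`` independent coalescent SMM
    loci; per-locus M-ratios (monomorphic loci -> 1) are averaged.
    """
    out = np.empty(n_sims)
    for s in range(n_sims):
        ms = np.empty(n_loci)
        for l in range(n_loci):
            tree = simulate_genealogy(n_genes, rng)
            alleles = smm_locus(tree, theta, rng)
            ms[l] = sumstats.m_ratio_locus(alleles)
        out[s] = ms.mean()
    return out


def _mean_K(theta: float, n_genes: int, rng: np.random.Generator,
            n_sims: int = 400,
            window: tuple[int, int] | None = None) -> float:
    ks = [np.unique(smm_locus(simulate_genealogy(n_genes, rng),
                              theta, rng, window=window)).size
          for _ in range(n_sims)]
    return float(np.mean(ks))


def matched_theta(k_observed: int, n_genes: int,
                  rng: np.random.Generator,
                  window: tuple[int, int] | None = None) -> float:
    """Theta whose expected SMM allele count equals the observed k.

    Moment-matching by stochastic bisection on a log scale, mirroring how
    the heterozygosity-excess machinery infers the scaled mutation rate
    from the data's allele count alone.
    """
    lo, hi = 0.01, 200.0
    for _ in range(18):
        mid = float(np.sqrt(lo * hi))
        if _mean_K(mid, n_genes, rng, window=window) < k_observed:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def estimate_Heq(
    n_genes: int,
    k_observed: int,
    rng: np.random.Generator,
    min_accepted: int = 500,
    max_sims: int = 500_000,
    window: tuple[int, int] | None = None,
) -> float:
    """Equilibrium expected heterozygosity given the observed allele count.

    Two stages: (1) match theta so the expected coalescent-SMM allele
    count equals ``k_observed``; (2) accept-reject at that theta, keeping
    loci whose simulated allele count equals ``k_observed`` exactly, and
    average their unbiased expected heterozygosities.  Conditioning on k,
    the near-sufficient statistic, is what the heterozygosity-excess test
    requires; the calibration keeps the test near its nominal level under
    Wright-Fisher equilibrium data.
    """
    if not 1 <= k_observed <= n_genes:
        raise ValueError("k_observed must be in [1, n_genes]")
    if k_observed == 1:
        return 0.0
    if window is not None and k_observed > window[1] - window[0] + 1:
        raise ValueError("k_observed exceeds the constrained allele window")
    theta = matched_theta(k_observed, n_genes, rng, window=window)
    accepted: list[float] = []
    total = 0
    while len(accepted) < min_accepted:
        if total >= max_sims:
            raise HeqEstimationError(
                f"only {len(accepted)} acceptances for k={k_observed} "
                f"(n={n_genes}) after {total} simulations"
            )
        alleles = smm_locus(simulate_genealogy(n_genes, rng), theta, rng,
                            window=window)
        if np.unique(alleles).size == k_observed:
            accepted.append(sumstats.expected_heterozygosity(alleles))
        total += 1
    return float(np.mean(accepted))


def tajima_null_distribution(
    n_segregating: int,
    n_genes: int,
    rng: np.random.Generator,
    n_sims: int = 1000,
) -> np.ndarray:
    """Null Tajima's D conditioned on the observed number of segregating sites.

    Hudson-style fixed-S simulations: each replicate draws a Kingman
    genealogy and places exactly ``n_segregating`` mutations on branches
    with probability proportional to branch length.  Conditioning on S
    removes the nuisance mutation parameter, as in the standard
    simulation-based significance test for D.
    """
    if n_segregating < 1:
        raise ValueError("need at least one segregating site")
    c = sumstats.tajima_constants(n_genes)
    var = (c["e1"] * n_segregating
           + c["e2"] * n_segregating * (n_segregating - 1))
    sd = float(np.sqrt(var))
    out = np.empty(n_sims)
    for s in range(n_sims):
        tree = simulate_genealogy(n_genes, rng)
        cum = np.cumsum(tree.branch_length)
        branches = np.searchsorted(
            cum, rng.uniform(0.0, cum[-1], size=n_segregating))
        counts = tree.leaves_below()[branches]
        pi = _pi_from_counts(counts, n_genes)
        out[s] = (pi - n_segregating / c["a1"]) / sd
    return out


class NullCache:
    """Memoized null distributions, reproducible independent of call order.

    Identical (n, k) pairs and identical theta values recur constantly
    across a grid run; every cache entry derives its own random stream from
    the cache seed and the entry key, so results do not depend on which
    cell asks first.
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self._null_m: dict[tuple, np.ndarray] = {}
        self._heq: dict[tuple, float] = {}

    def _rng(self, *key_ints: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, *[int(k) for k in key_ints]]))

    def null_m(self, theta: float, n_genes: int, n_loci: int,
               n_sims: int = 1000) -> np.ndarray:
        key = (round(theta, 12), n_genes, n_loci, n_sims)
        if key not in self._null_m:
            rng = self._rng(1, int(theta * 10**9), n_genes, n_loci, n_sims)
            self._null_m[key] = null_M_distribution(
                theta, n_genes, n_loci, rng, n_sims=n_sims)
        return self._null_m[key]

    def heq(self, n_genes: int, k_observed: int,
            min_accepted: int = 500,
            window: tuple[int, int] | None = None) -> float:
        key = (n_genes, k_observed, min_accepted, window)
        if key not in self._heq:
            wkey = [3, window[0], window[1]] if window else []
            rng = self._rng(2, n_genes, k_observed, min_accepted, *wkey)
            self._heq[key] = estimate_Heq(
                n_genes, k_observed, rng, min_accepted=min_accepted,
                window=window)
        return self._heq[key]
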