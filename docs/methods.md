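# Methods

## The question

Bottleneck-detection tests (the M-ratio, the heterozygosity-excess test,
Tajima's *D*, and model-based size-change estimators) assume a stable
Wright–Fisher population: Poisson-distributed family sizes, i.e. variance
in reproductive success V_k = 2 at mean 2. Many high-fecundity organisms
violate this badly — a few "winners" leave most of the offspring
(sweepstakes reproductive success). This package asks: **how often do the
standard tests report a bottleneck in a demographically stable population
whose only non-ideal feature is large V_k?** The fraction of stable
replicates called significant is the false positive rate (FPR, type-I
error).

## Demographic model

Diploid, hermaphroditic, constant census size N_c, non-overlapping
generations. Each generation the parents are shuffled into N_c/2 disjoint
pairs; each pair draws a family size from the offspring model; families
fill the next generation in pair order and the last family is truncated so
the census is exactly constant (if a pass of pairs falls short, parents are
re-paired and drawing continues). Because each parent belongs to exactly
one pair, the per-parent offspring variance equals the family-size
variance, which is what the classical mapping

    N_e / N_c = 4 / (V_k + 2)

assumes. Grid cells are specified by the *effective* size N_e (50, 500,
2500, 5000) and V_k (2, 40, 400, 2000); the census is derived, rounded to
the nearest even integer. At V_k = 2 family sizes are Poisson(2) and
N_c = N_e; larger V_k uses a floored gamma.

### The floored-gamma offspring model

Family size X = floor(Gamma(shape, scale)). The two gamma parameters are
free and solved by 2-D root finding so that the *discrete* distribution has
mean 2 (within 1%) and variance V_k (within 5%); moments are computed by
analytic summation of P(X=k) = F(k+1) − F(k) with the support truncated at
tail mass 1e-12, so the calibration is deterministic. The result is
negative-binomial-like: at V_k = 400 about 95% of pairs leave no offspring
and the largest of the ~25 000 families at N_c = 50 250 reaches ~1500
offspring.

## Mutation models

* **Microsatellites** (15 unlinked loci, mu = 5e-4 per locus per
  generation): strict stepwise mutation (SMM), ±1 repeat with equal
  probability. Equilibrium heterozygosity has the closed form
  He = 1 − 1/sqrt(1 + 2 theta), theta = 4 N_e mu — the main simulator
  calibration anchor (0.087 at N_e=50, 0.423 at N_e=500).
* **Constrained microsatellites**: SMM reflected inside a window of 5
  adjacent repeat states (EST-like loci with restricted allelic range).
* **DNA sequences**: one 500-bp fragment, infinite-sites, mu = 1e-7 per
  site per generation (theta = 0.1 per fragment at N_e=500). Mutations are
  tracked as abstract sites — each mutation is a new site by construction,
  which enforces the infinite-sites property exactly; a sampled dataset
  maps its segregating mutations to concrete positions. At theta = 0.1
  most 100-sequence samples carry S = 0 and Tajima's D is undefined; such
  replicates are excluded from mean-D and FPR denominators and their count
  is reported.

## Initialization and burn-in

Populations start at (approximate) mutation–drift equilibrium: for each
locus a Kingman-coalescent sample of 200 gene copies at the configured
theta renders the stationary allele-frequency cloud — including its
rare-allele scatter and, for sequences, the stationary haplotype
structure — and every population gene copy draws i.i.d. from that founder
pool. The population is then burned in for N_e further generations under
the *actual* offspring model, with K (allele count), He, and F_is recorded
every 50 generations; convergence is declared when the least-squares slope
of the second half of the He trajectory is below 5e-4 per generation
(non-convergence is reported, never fatal).

Why not a Dirichlet start: a diffuse Dirichlet over 10 repeat states
begins at He ≈ 0.82, and with relaxation rate 1/(2 N_e) + 2 mu an
N_e-generation burn-in retains ~40% of the excess; a compact start instead
under-builds the allele-size scatter that the M-ratio is sensitive to.
Equilibrium-rendered founders remove the dilemma. A Dirichlet
initialization remains available as an option.

## Sampling: cohorts, not uniform draws

The study condition samples n = 50 individuals as a **local cohort of
whole sibships**: offspring arrays are filled family-by-family in random
family order, and the first 50 individuals are taken. With Poisson
reproduction this is ~25 families and practically indistinguishable from a
uniform draw. Under sweepstakes reproduction a cohort is a handful of
large broods — the realistic field situation for high-fecundity species
(a catch of larvae or seedlings is dominated by few families).

This choice is load-bearing, so its rationale is spelled out. With family
sizes of mean 2 and variance V_k at census N_e(V_k+2)/4, the probability
that two *uniformly* sampled individuals are siblings is exactly 2/N_e —
pinned by the coalescent definition of N_e regardless of V_k. At N_e=500 a
uniform sample of 50 therefore contains ~5 sibling pairs whether V_k is 2
or 2000, and shows no sample-level distortion at all (verified: F_is ≈
0.000, M ≈ 0.98 at V_k=400). The V_k-dependent signals — negative F_is,
depressed M, positive Tajima's D, heterozygosity excess — all require
sibship clustering *within the sample*, and a cohort sample supplies
exactly that with no free parameter. Uniform sampling
(`sample_individuals`) is retained and used for the equilibrium
validations, where the closed forms describe random samples.

## The four tests

All tests are one-sided toward the bottleneck signature; alpha = 0.05.

* **M-ratio, fixed threshold**: per locus M = (occupied repeat states) /
  (max − min + 1); monomorphic loci contribute M = 1; bottleneck called
  when the dataset mean is strictly below 0.68.
* **M-ratio, simulated critical value**: the null of the dataset-mean M is
  rebuilt from 1000 Kingman-coalescent SMM datasets (same locus and gene
  counts) at theta = 4 N_e mu using the *true* generating values; the
  critical value is the lower-tail empirical 5% order statistic without
  interpolation.
* **Heterozygosity excess**: per polymorphic locus the unbiased Nei
  estimator He = n/(n−1) (1 − Σp²) is compared with Heq, the equilibrium
  heterozygosity expected for the observed allele count k: theta is first
  matched so that E[K] = k (stochastic bisection), then coalescent SMM
  simulations at that theta are accepted when K = k exactly and their He
  averaged (≥500 acceptances). For constrained loci the same machinery
  runs with the reflected 5-state window, keeping the test near nominal
  level at V_k = 2. Loci-level differences He − Heq enter a one-tailed
  Wilcoxon signed-rank (exact for ≤25 informative loci, zeros dropped);
  fewer than 4 polymorphic loci → test not applicable.
* **Tajima's D**: D = (pi − S/a1) / sqrt(e1 S + e2 S(S−1)) with the
  standard constants; undefined at S = 0. Significance by Hudson-style
  fixed-S simulation: 1000 genealogies each receive exactly S mutations
  (branch chosen proportional to length); p is the fraction with simulated
  D ≥ observed. Conditioning on S (rather than plugging in theta-hat = pi)
  removes the nuisance mutation parameter and matches the behavior of the
  standard simulation-based test; with theta-hat = pi the most extreme
  S = 1 configuration would sit permanently at p ≈ 0.051.

Null distributions are memoized per (theta, locus count, gene count) and
Heq per (gene count, k, window); every cache entry derives its random
stream from the cache seed plus the entry key, so results are independent
of call order and bit-reproducible under a master seed.

## Orchestration and problem sizes

`experiment.run_cell` runs one (N_e, V_k, marker) cell: calibrate →
initialize → burn in N_e generations → cohort-sample 50 → battery;
replicate seeds are spawned from a master seed. Aggregates report means
and SDs of He, Ho, K, F_is, M, %P (share of loci with K ≥ 2), and per-test
FPR with Clopper–Pearson 95% intervals over the replicates where the test
was applicable.

Default desk-scale runs use 20–30 replicates per microsatellite cell
(about 8 s per replicate at the largest desk census, N_c = 50 250,
vectorized over a (N_c × 15 × 2) genotype array) and 60–80 sequence
replicates (cheap; the haplotype state is two integers per individual).
The full 100-replicate, 16-cell grid of the study design is available via
`GridSpec(full=True)`; its N_e ∈ {2500, 5000} × V_k ∈ {400, 2000} cells
forward-simulate censuses up to 2.5 million and are excluded from the desk
profile.

## What the synthetic data do and do not emulate

Emulated: constant census, random (monogamous) mating, the target
family-size variance, SMM/infinite-sites mutation, equilibrium start,
cohort sampling. Not emulated: selection, migration, overlapping
generations, separate sexes, linked loci, genotyping error, and multi-step
microsatellite mutation. Passing tests therefore show how the *tests*
behave when their Poisson assumption alone is violated; they do not
certify behavior on real data where these other features co-occur.

## Known limitations and honest misfits

* At strict SMM equilibrium with matched theta, even a sample whose
  genealogy collapses to ~12 effective gene copies has E[M] ≈ 0.956
  (coalescent computation). Reference values for the N_e=500, V_k=400
  condition (M ≈ 0.87 with K ≈ 2.9 — more alleles *and* more gaps than
  equilibrium SMM allows simultaneously) are not reachable by this model
  at that cell; the M-based false positive rates we measure there
  (fixed-threshold ≈ 0, simulated-critical ≈ 0.2–0.4) are correspondingly
  lower than those reference values, while F_is, the heterozygosity-excess
  and Tajima's D behavior, and the constrained-locus contrast reproduce
  well. The package reports what the model actually produces.
* The cohort sample size (50) interacts with the family-size tail; cohort
  composition is in whole broods, with the last brood truncated at 50.
* Heq conditioning on k alone is only approximately calibrated (measured
  null FPR 0.06 at nominal 0.05, theta = 1).
* The N_e/N_c mapping is itself an approximation; realized per-parent
  variance is further deformed slightly (a few percent) by the
  truncation that enforces exact census constancy.
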