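"""Family-size (offspring-number) distributions and the N_e/N_c mapping.

A demographically stable population with mean two offspring per mating can
still experience strong genetic drift if the variance in reproductive
success, ``V_k``, exceeds the Poisson value of 2.  The classical
approximation linking the effective and census sizes under non-Poisson
reproduction is ``N_e / N_c = 4 / (V_k + 2)``.

Two family-size models are provided:

* ``poisson`` — Poisson(2); the Wright–Fisher baseline, V_k = 2 exactly.
* ``floored_gamma`` — ``floor(Gamma(shape, scale))``, calibrated so the
  discrete distribution has mean 2 and variance V_k.  The floor produces a
  heavy right tail and a large mass at zero ("many losers, few winners").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "OffspringModel",
    "DemographyConfig",
    "CalibrationError",
    "ne_nc_ratio",
    "census_size",
    "calibrate_floored_gamma",
    "poisson_model",
    "draw_family_sizes",
    "floored_gamma_pmf",
]

#: mean offspring per mating, fixed by the stable-population constraint
FAMILY_MEAN = 2.0

#: tail mass below which the discretized gamma support is truncated
_TAIL_EPS = 1e-12


class CalibrationError(RuntimeError):
    """Raised when no (shape, scale) pair attains the requested moments."""


@dataclass(frozen=True)
class OffspringModel:
    """A calibrated discrete family-size distribution.

    Attributes
    ----------
    family_mean : float
        Target expected offspring per mating (always 2).
    family_variance : float
        Target variance V_k.
    kind : str
        ``"poisson"`` or ``"floored_gamma"``.
    shape_param, scale_param : float
        Gamma parameters (floored_gamma only; NaN for Poisson).
    realized_mean, realized_variance : float
        Analytic moments of the discrete (floored) distribution.
    """

    family_mean: float
    family_variance: float
    kind: str
    shape_param: float
    scale_param: float
    realized_mean: float
    realized_variance: float


@dataclass(frozen=True)
class DemographyConfig:
    """One grid cell of the simulation study.

    ``census_size`` is derived from ``effective_size`` and ``variance`` via
    N_c = N_e (V_k + 2)/4, rounded to the nearest even integer (mating is by
    disjoint pairs, so the census must be even).
    """

    effective_size: int
    variance: float
    n_loci: int = 15
    mutation_rate: float = 5e-4
    sample_size: int = 50
    marker_type: str = "microsat"  # microsat | microsat_constrained | sequence

    @property
    def census_size(self) -> int:
        nc = int(round(self.effective_size * (self.variance + 2.0) / 4.0))
        if nc % 2:
            nc += 1
        return max(nc, 2)

    @property
    def theta(self) -> float:
        """Population-mutation parameter 4 N_e mu (per locus)."""
        return 4.0 * self.effective_size * self.mutation_rate

    def __post_init__(self) -> None:
        if self.effective_size < 1:
            raise ValueError("effective_size must be >= 1")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")
        if self.sample_size > self.census_size:
            raise ValueError(
                f"sample_size {self.sample_size} exceeds census size "
                f"{self.census_size}"
            )


def ne_nc_ratio(v_k: float) -> float:
    """Ratio of effective to census size implied by family-size variance.

    Returns 4/(V_k + 2).  Only V_k >= 2 yields a ratio <= 1; smaller
    variances are outside the model's intended use and raise.
    """
    if v_k < 0:
        raise ValueError("V_k must be non-negative")
    if v_k < 2:
        raise ValueError("V_k < 2 implies N_e > N_c; unsupported regime")
    return 4.0 / (v_k + 2.0)


def census_size(effective_size: int, v_k: float) -> int:
    """Census size N_c giving effective size N_e at reproductive variance V_k."""
    return DemographyConfig(effective_size=effective_size, variance=v_k,
                            sample_size=2).census_size


def floored_gamma_pmf(shape: float, scale: float) -> np.ndarray:
    """Probability mass function of floor(Gamma(shape, scale)).

    P(X = k) = F(k+1) - F(k); the support is truncated where the survival
    function drops below 1e-12, so the returned vector sums to 1 within
    that tail mass.
    """
    kmax = int(np.ceil(stats.gamma.isf(_TAIL_EPS, a=shape, scale=scale))) + 1
    edges = np.arange(kmax + 1, dtype=float)
    cdf = stats.gamma.cdf(edges, a=shape, scale=scale)
    return np.diff(np.append(cdf, 1.0))


def _floored_moments(shape: float, scale: float) -> tuple[float, float]:
    pmf = floored_gamma_pmf(shape, scale)
    k = np.arange(pmf.size, dtype=float)
    mean = float(pmf @ k)
    var = float(pmf @ (k - mean) ** 2)
    return mean, var


def calibrate_floored_gamma(
    target_variance: float,
    tolerance: float = 1e-6,
    mean: float = FAMILY_MEAN,
) -> OffspringModel:
    """Solve for gamma (shape, scale) so floor(Gamma) has the target moments.

    The two moments of the floored distribution are computed by analytic
    summation of the discretized mass function and matched to
    (``mean``, ``target_variance``) by root finding in log-parameters.
    """
    if tolerance <= 0:
        raise CalibrationError("tolerance must be strictly positive")
    if target_variance <= mean:
        raise CalibrationError(
            "floored-gamma calibration requires variance above the mean "
            "(use the Poisson model for V_k = 2)"
        )

    # flooring removes ~0.5 from the mean, so aim the continuous gamma higher
    m0, v0 = mean + 0.5, target_variance
    x0 = np.log([m0 * m0 / v0, v0 / m0])

    def resid(logp: np.ndarray) -> np.ndarray:
        m, v = _floored_moments(*np.exp(logp))
        return np.array([m - mean, (v - target_variance) / target_variance])

    sol = optimize.root(resid, x0, method="hybr", tol=1e-12)
    shape, scale = np.exp(sol.x)
    rmean, rvar = _floored_moments(shape, scale)
    if (abs(rmean - mean) > max(tolerance, 0.01 * mean)
            or abs(rvar - target_variance) > max(
                tolerance * target_variance, 0.05 * target_variance)):
        raise CalibrationError(
            f"calibration failed for V_k={target_variance}: "
            f"realized mean {rmean:.4f}, variance {rvar:.2f} "
            f"(solver message: {sol.message})"
        )
    return OffspringModel(
        family_mean=mean,
        family_variance=target_variance,
        kind="floored_gamma",
        shape_param=float(shape),
        scale_param=float(scale),
        realized_mean=rmean,
        realized_variance=rvar,
    )


def poisson_model(mean: float = FAMILY_MEAN) -> OffspringModel:
    """The Wright–Fisher baseline: Poisson(2) family sizes, V_k = 2."""
    return OffspringModel(
        family_mean=mean,
        family_variance=mean,
        kind="poisson",
        shape_param=float("nan"),
        scale_param=float("nan"),
        realized_mean=mean,
        realized_variance=mean,
    )


def offspring_model_for(v_k: float, tolerance: float = 1e-6) -> OffspringModel:
    """Dispatch: Poisson for V_k = 2, calibrated floored gamma otherwise."""
    if v_k == 2:
        return poisson_model()
    return calibrate_floored_gamma(v_k, tolerance=tolerance)


def draw_family_sizes(
    model: OffspringModel, n_families: int, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. family sizes from a calibrated model (non-negative integers)."""
    if n_families == 0:
        return np.zeros(0, dtype=np.int64)
    if model.kind == "poisson":
        return rng.poisson(model.family_mean, size=n_families)
    return np.floor(
        rng.gamma(model.shape_param, model.scale_param, size=n_families)
    ).astype(np.int64)
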