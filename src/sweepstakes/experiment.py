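"""Grid orchestration: simulate cells of (N_e, V_k), run the battery,
aggregate false positive rates.

Every simulated population is demographically stable, so any bottleneck
call is a false positive; the per-cell FPR is the fraction of replicates a
test calls, over the replicates where the test was applicable.  Replicates
draw independent seeds from a master seed, so a whole grid is bit-for-bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import battery, coalescent, forward, sumstats
from .offspring import DemographyConfig, offspring_model_for

__all__ = ["GridSpec", "CellResult", "run_cell", "run_grid",
           "binomial_ci", "DESK_SCALE_EXCLUDED"]

#: cells whose census (up to 2.5M) is beyond a desk-scale forward run
DESK_SCALE_EXCLUDED = {(ne, vk) for ne in (2500, 5000) for vk in (400, 2000)}

_TESTS = ("m_ratio_ft", "m_ratio_sim", "het_excess", "tajima")


@dataclass(frozen=True)
class GridSpec:
    """The study grid; defaults follow the primary simulation design."""

    ne_values: tuple[int, ...] = (50, 500, 2500, 5000)
    vk_values: tuple[float, ...] = (2, 40, 400, 2000)
    replicates: int = 100
    marker_type: str = "microsat"
    n_loci: int = 15
    mutation_rate: float = 5e-4
    sample_size: int = 50
    alpha: float = 0.05
    seed: int = 0
    full: bool = False  # include the census>1M cells

    def cells(self) -> list[tuple[int, float]]:
        out = []
        for ne in self.ne_values:
            for vk in self.vk_values:
                if not self.full and (ne, vk) in DESK_SCALE_EXCLUDED:
                    continue
                out.append((ne, vk))
        return out


@dataclass
class CellResult:
    ne: int
    vk: float
    marker_type: str
    replicates: pd.DataFrame          # one row per replicate
    summary: dict = field(default_factory=dict)


def binomial_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval for a proportion."""
    if n == 0:
        return (0.0, 1.0)
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.isf(alpha / 2, k + 1, n - k))
    return lo, hi


def _replicate_row(ds, diag, res: battery.TestBatteryResult) -> dict:
    row: dict = {"replicate": ds.replicate_id, "seed": ds.seed,
                 "converged": diag.converged}
    if ds.marker_type == "sequence":
        stats = sumstats.sequence_summary(ds.genotypes)
        row.update(S=stats.seg_sites, pi=stats.pi, tajima_d=stats.tajima_d)
    else:
        stats = sumstats.microsat_summary(ds.genotypes)
        row.update(he=stats.het_expected, ho=stats.het_observed,
                   k=stats.n_alleles, fis=stats.f_is, m=stats.m_ratio,
                   pct_p=stats.pct_polymorphic)
    for name in _TESTS:
        tr = getattr(res, name)
        if tr is None:
            continue
        row[f"{name}_call"] = bool(tr.call)
        row[f"{name}_applicable"] = bool(tr.applicable)
        if tr.p_value is not None:
            row[f"{name}_p"] = tr.p_value
    return row


def run_cell(
    ne: int,
    vk: float,
    replicates: int,
    marker_type: str = "microsat",
    seed: int = 0,
    alpha: float = 0.05,
    n_loci: int = 15,
    mutation_rate: float = 5e-4,
    sample_size: int = 50,
    cache: coalescent.NullCache | None = None,
    n_null_sims: int = 1000,
    burnin_generations: int | None = None,
) -> CellResult:
    """Simulate one (N_e, V_k) cell and run the battery on every replicate."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if marker_type == "sequence":
        n_loci, mutation_rate = 1, 1e-7
    config = DemographyConfig(
        effective_size=ne, variance=vk, n_loci=n_loci,
        mutation_rate=mutation_rate, sample_size=sample_size,
        marker_type=marker_type,
    )
    model = offspring_model_for(vk)
    if cache is None:
        cache = coalescent.NullCache(seed)

    marker_code = {"microsat": 0, "microsat_constrained": 1, "sequence": 2}
    root = np.random.SeedSequence(
        [seed, ne, int(vk), marker_code[marker_type]])
    rows = []
    for rep, child in enumerate(root.spawn(replicates)):
        rep_seed = int(child.generate_state(1, dtype=np.uint32)[0])
        ds, diag = forward.simulate_replicate(
            config, model, rep_seed, replicate_id=rep,
            burnin_generations=burnin_generations,
        )
        test_rng = np.random.default_rng(
            np.random.SeedSequence([seed, ne, int(vk),
                                    marker_code[marker_type], 77, rep]))
        res = battery.run_battery(
            ds, true_ne=ne, true_mu=mutation_rate,
            cache=cache, rng=test_rng, alpha=alpha, n_sims=n_null_sims,
        )
        rows.append(_replicate_row(ds, diag, res))
    df = pd.DataFrame(rows)

    summary: dict = {"ne": ne, "vk": vk, "marker_type": marker_type,
                     "ne_nc": 4.0 / (vk + 2.0),
                     "n_replicates": replicates}
    for col in ("he", "k", "fis", "m", "pct_p", "tajima_d", "pi", "S"):
        if col in df:
            vals = df[col].dropna()
            summary[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
            summary[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            summary[f"{col}_n"] = int(len(vals))
    for name in _TESTS:
        call_col = f"{name}_call"
        if call_col not in df:
            continue
        ok = df[f"{name}_applicable"]
        n_valid = int(ok.sum())
        n_calls = int(df.loc[ok, call_col].sum())
        fpr = n_calls / n_valid if n_valid else np.nan
        lo, hi = binomial_ci(n_calls, n_valid)
        summary[f"fpr_{name}"] = fpr
        summary[f"fpr_{name}_lo"] = lo
        summary[f"fpr_{name}_hi"] = hi
        summary[f"fpr_{name}_n"] = n_valid
    return CellResult(ne=ne, vk=vk, marker_type=marker_type,
                      replicates=df, summary=summary)


def run_grid(
    spec: GridSpec,
    cache: coalescent.NullCache | None = None,
) -> pd.DataFrame:
    """Map :func:`run_cell` over the grid; one summary row per cell."""
    if cache is None:
        cache = coalescent.NullCache(spec.seed)
    rows = []
    for ne, vk in spec.cells():
        cell = run_cell(
            ne, vk, spec.replicates, marker_type=spec.marker_type,
            seed=spec.seed, alpha=spec.alpha, n_loci=spec.n_loci,
            mutation_rate=spec.mutation_rate, sample_size=spec.sample_size,
            cache=cache,
        )
        rows.append(cell.summary)
    return pd.DataFrame(rows)


def format_fpr_table(df: pd.DataFrame) -> str:
    """Human-readable report mirroring the study's table layout."""
    cols = ["ne", "vk", "ne_nc", "he_mean", "he_sd", "k_mean", "k_sd",
            "fis_mean", "fis_sd", "m_mean", "m_sd", "pct_p_mean",
            "fpr_m_ratio_ft", "fpr_m_ratio_sim", "fpr_het_excess"]
    present = [c for c in cols if c in df.columns]
    return df[present].to_string(index=False, float_format=lambda x: f"{x:.3f}")
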