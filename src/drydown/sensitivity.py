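"""Variance-based global sensitivity analysis of dehydration times.

Saltelli sampling (scrambled Sobol' low-discrepancy sequences) combined with
the Jansen estimator of total-order indices: for each parameter ``i``,

    S_Ti = (1/(2N)) * sum_j (f(A_j) - f(AB_i,j))^2 / Var(f)

where ``A`` and ``B`` are two quasi-random sample matrices and ``AB_i`` is
``A`` with column ``i`` replaced from ``B`` — ``N*(k+2)`` model evaluations
for ``k`` parameters.  Traits are perturbed uniformly within +/-10% of their
species mean (the bounds fraction is configurable), every design row is one
full dry-down simulation under the standardized leaf area / pot volume and
the constant synthetic summer-day climate, and indices are reported per
response metric (T_close, T_cav, THF) with bootstrap confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .architecture import DEFAULT_K_PLANT, SoilParams, build_fractal_tree
from .climate import ClimateSeries, synthesize_climate
from .metrics import dehydration_times
from .simulator import (STANDARD_LEAF_AREA, STANDARD_POT_VOLUME, SimOptions,
                        run_dehydration)
from .traits import SpeciesTraits

__all__ = ["SobolDesign", "SobolResult", "saltelli_design",
           "sobol_total_indices", "run_sensitivity",
           "DEFAULT_SENSITIVITY_PARAMS"]

#: Default perturbed-parameter subset: every trait reported as contributing
#: >10% of variance to at least one dehydration time, plus the storage and
#: conductance parameters the compartment model adds.
DEFAULT_SENSITIVITY_PARAMS = (
    "pi0", "epsilon", "gs_max", "g_res", "q10_a", "q10_b", "t_p",
    "p50", "vc_slope", "apoplastic_fraction", "symplast_volume_per_area",
    "k_plant",
)


@dataclass
class SobolDesign:
    names: list[str]
    base: np.ndarray  # (k,) base values
    lower: np.ndarray  # (k,)
    upper: np.ndarray  # (k,)
    n: int
    seed: int
    a: np.ndarray  # (N, k)
    b: np.ndarray  # (N, k)
    ab: np.ndarray  # (k, N, k): A with column i from B

    @property
    def n_evaluations(self) -> int:
        return self.n * (len(self.names) + 2)

    def rows(self) -> np.ndarray:
        """All evaluation rows stacked: A, B, AB_1..AB_k — shape (N*(k+2), k)."""
        return np.vstack([self.a, self.b, self.ab.reshape(-1, len(self.names))])


@dataclass
class SobolResult:
    """Total-order indices for one response metric."""

    metric: str
    names: list[str]
    s_total: np.ndarray  # (k,)
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int
    seed: int
    failed_runs: int  # rows imputed by the response median

    def ranked(self) -> pd.DataFrame:
        df = pd.DataFrame({"parameter": self.names, "s_total": self.s_total,
                           "ci_low": self.ci_low, "ci_high": self.ci_high})
        return df.sort_values("s_total", ascending=False).reset_index(drop=True)

    def top(self, k: int = 1) -> list[str]:
        return list(self.ranked()["parameter"].head(k))


def saltelli_design(names: Sequence[str], base: Sequence[float], n: int,
                    seed: int, bounds_fraction: float = 0.10,
                    lower: Optional[Sequence[float]] = None,
                    upper: Optional[Sequence[float]] = None) -> SobolDesign:
    """Build the Saltelli evaluation design for ``k`` parameters.

    ``n`` must be a power of two (balanced Sobol' sequences).  Bounds default
    to ``base * (1 -/+ bounds_fraction)``, ordered so lower < upper for
    negative base values as well.
    """
    k = len(names)
    if k < 1:
        raise ValueError("need at least one parameter")
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError(f"N must be a power of 2, got {n}")
    base = np.asarray(base, float)
    if lower is None or upper is None:
        lo = base * (1.0 - bounds_fraction)
        hi = base * (1.0 + bounds_fraction)
        lower = np.minimum(lo, hi)
        upper = np.maximum(lo, hi)
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)

    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
    u = sampler.random_base2(int(math.log2(n)))
    a = lower + u[:, :k] * (upper - lower)
    b = lower + u[:, k:] * (upper - lower)
    ab = np.repeat(a[None, :, :], k, axis=0)
    for i in range(k):
        ab[i, :, i] = b[:, i]
    return SobolDesign(names=list(names), base=base, lower=lower, upper=upper,
                       n=n, seed=seed, a=a, b=b, ab=ab)


def sobol_total_indices(design: SobolDesign, outputs: np.ndarray,
                        metric: str = "y", n_boot: int = 200,
                        max_failed_fraction: float = 0.10,
                        rng: Optional[np.random.Generator] = None) -> SobolResult:
    """Jansen total-order indices from outputs over ``design.rows()``.

    ``outputs`` is the flat vector of model evaluations in row order
    (A block, B block, then the k AB blocks).  Non-finite outputs (failed
    runs) are imputed by the finite-response median and counted; more than
    ``max_failed_fraction`` failures is an error (design too wide or model
    unstable).  Bootstrap CIs (percentile, 2.5/97.5) resample sample rows.
    """
    k = len(design.names)
    n = design.n
    y = np.asarray(outputs, float).copy()
    if y.shape != (n * (k + 2),):
        raise ValueError(f"expected {n * (k + 2)} outputs, got {y.shape}")
    bad = ~np.isfinite(y)
    failed = int(bad.sum())
    if failed > max_failed_fraction * len(y):
        raise ValueError(
            f"{failed}/{len(y)} failed runs exceeds the "
            f"{max_failed_fraction:.0%} limit: design too wide or model unstable")
    if failed:
        y[bad] = float(np.median(y[~bad]))

    f_a = y[:n]
    f_b = y[n:2 * n]
    f_ab = y[2 * n:].reshape(k, n)

    def jansen(idx: np.ndarray) -> np.ndarray:
        var = np.var(np.concatenate([f_a[idx], f_b[idx]]))
        if var <= 0:
            return np.zeros(k)
        return np.mean((f_a[idx][None, :] - f_ab[:, idx]) ** 2, axis=1) / (2.0 * var)

    all_idx = np.arange(n)
    s_t = jansen(all_idx)
    rng = rng if rng is not None else np.random.default_rng(design.seed + 1)
    boots = np.empty((n_boot, k))
    for bi in range(n_boot):
        boots[bi] = jansen(rng.integers(0, n, size=n))
    ci_low = np.percentile(boots, 2.5, axis=0)
    ci_high = np.percentile(boots, 97.5, axis=0)
    return SobolResult(metric=metric, names=list(design.names), s_total=s_t,
                       ci_low=ci_low, ci_high=ci_high, n=n, seed=design.seed,
                       failed_runs=failed)


def _evaluate_row(traits: SpeciesTraits, soil: SoilParams, names: list[str],
                  row: np.ndarray, climate: ClimateSeries,
                  options: SimOptions) -> tuple[float, float, float]:
    values = dict(zip(names, (float(v) for v in row)))
    k_plant = values.pop("k_plant", DEFAULT_K_PLANT)
    tr = traits.perturbed(**values) if values else traits
    net = build_fractal_tree(tr, k_plant=k_plant)
    traj = run_dehydration(tr, net, soil, climate, options)
    m = dehydration_times(traj, tr)
    return m.t_close, m.t_cav, m.thf


def run_sensitivity(traits: SpeciesTraits,
                    params: Sequence[str] = DEFAULT_SENSITIVITY_PARAMS,
                    n: int = 128, seed: int = 0,
                    climate: Optional[ClimateSeries] = None,
                    options: Optional[SimOptions] = None,
                    soil: Optional[SoilParams] = None,
                    bounds_fraction: float = 0.10,
                    std_leaf_area: float = STANDARD_LEAF_AREA,
                    std_pot_volume: float = STANDARD_POT_VOLUME,
                    progress: Optional[Callable[[int, int], None]] = None,
                    ) -> dict[str, SobolResult]:
    """Sobol total-order sensitivity of T_close, T_cav and THF for one species.

    The species is standardized to the common leaf area and pot volume, and
    dried down under the constant summer-day climate; each of the
    ``n * (k + 2)`` design rows is a full simulation.  Returns one
    :class:`SobolResult` per metric keyed ``t_close`` / ``t_cav`` / ``thf``.
    """
    base_traits = traits.perturbed(leaf_area=std_leaf_area)
    soil = soil if soil is not None else SoilParams(pot_volume=std_pot_volume)
    options = options if options is not None else SimOptions(
        dt_max=1800.0, max_days=120)
    max_days = options.max_days if options.max_days is not None else 120
    climate = climate if climate is not None else synthesize_climate(
        days=max_days + 1)

    base_values = []
    for p in params:
        if p == "k_plant":
            base_values.append(DEFAULT_K_PLANT)
        else:
            base_values.append(getattr(base_traits, p))
    design = saltelli_design(params, base_values, n=n, seed=seed,
                             bounds_fraction=bounds_fraction)

    rows = design.rows()
    outs = np.empty((len(rows), 3))
    for j, row in enumerate(rows):
        outs[j] = _evaluate_row(base_traits, soil, list(params), row, climate,
                                options)
        if progress is not None:
            progress(j + 1, len(rows))

    results = {}
    for col, metric in enumerate(("t_close", "t_cav", "thf")):
        results[metric] = sobol_total_indices(design, outs[:, col],
                                              metric=metric)
    return results


def result_table(results: dict[str, SobolResult]) -> pd.DataFrame:
    """Long-format CSV-ready table: metric, parameter, S_T, CI, N, seed."""
    rows = []
    for metric, res in results.items():
        for i, name in enumerate(res.names):
            rows.append({"metric": metric, "parameter": name,
                         "s_total": res.s_total[i], "ci_low": res.ci_low[i],
                         "ci_high": res.ci_high[i], "n": res.n,
                         "seed": res.seed, "failed_runs": res.failed_runs})
    return pd.DataFrame(rows)
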