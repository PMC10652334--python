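"""Dehydration-time metrics and model-vs-observation comparison.

The three response variables of a dry-down trajectory:

* ``t_close`` — days from full hydration to stomatal closure, defined
  operationally as an 88% reduction of midday transpiration relative to the
  trajectory's maximum midday value (the P_gs88 convention, applied to the
  trajectory itself so the metric stays self-consistent when traits are
  perturbed);
* ``t_cav`` — days from stomatal closure to hydraulic failure, the water
  potential at 99% loss of leaf hydraulic conductivity;
* ``thf = t_close + t_cav`` — overall time to hydraulic failure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .physiology import psi_at_plc
from .simulator import SimTrajectory
from .traits import SpeciesTraits

__all__ = ["DehydrationMetrics", "dehydration_times", "daily_extremes",
           "compare_to_observations", "CLOSURE_E_FRACTION", "FAILURE_PLC"]

#: Fraction of maximum midday E remaining at "stomatal closure" (88% reduction).
CLOSURE_E_FRACTION = 0.12
#: PLC (%) defining hydraulic failure.
FAILURE_PLC = 99.0


@dataclass(frozen=True)
class DehydrationMetrics:
    t_close: float  # days (nan if closure never reached)
    t_cav: float  # days (nan if failure never reached)
    thf: float  # days (nan if failure never reached)
    psi_min: float  # MPa, minimum leaf water potential over the run
    psi_close: float  # MPa, leaf psi at the closure crossing (nan if unreached)
    psi_fail: float  # MPa, the 99%-PLC threshold used
    reached_close: bool
    reached_failure: bool


def _first_crossing(times: np.ndarray, values: np.ndarray,
                    threshold: float, falling: bool = True) -> float:
    """Linear-interpolated first crossing time; nan if never crossed."""
    v = values - threshold
    if falling:
        hit = v <= 0.0
    else:
        hit = v >= 0.0
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        return math.nan
    i = int(idx[0])
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = v[i - 1], v[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (t1 - t0) * (0.0 - v0) / (v1 - v0))


def daily_extremes(traj: SimTrajectory | pd.DataFrame) -> pd.DataFrame:
    """Per-day predawn/midday water potentials and midday transpiration.

    Predawn is the 05:00 sample; midday values are means over 12:00-14:00
    (the 2 h window around midday).  Days with missing hours are skipped with
    a warning.  Midday E is total water loss (stomatal + residual + bark),
    the quantity a balance would record.
    """
    df = traj.data if isinstance(traj, SimTrajectory) else traj
    t = df["time"].to_numpy(float)
    day = np.floor(t / 24.0).astype(int)
    hour = t - day * 24.0
    e_total = (df["e_canopy"] + df["e_residual"]).to_numpy(float)
    psi_leaf = df["psi_leaf"].to_numpy(float)

    out = []
    for d in np.unique(day):
        sel = day == d
        h = hour[sel]
        pre_mask = np.isclose(h, 5.0)
        mid_mask = (h >= 12.0) & (h <= 14.0)
        if not pre_mask.any() or not mid_mask.any():
            warnings.warn(f"day {d}: missing predawn or midday hours, skipped")
            continue
        out.append({
            "day": int(d),
            "predawn_psi": float(psi_leaf[sel][pre_mask][0]),
            "midday_psi": float(psi_leaf[sel][mid_mask].mean()),
            "midday_e": float(e_total[sel][mid_mask].mean()),
        })
    return pd.DataFrame(out)


def dehydration_times(traj: SimTrajectory,
                      traits: Optional[SpeciesTraits] = None) -> DehydrationMetrics:
    """Extract T_close, T_cav and THF from a dry-down trajectory.

    The closure time is the first crossing of the midday-E series below 12%
    of its trajectory maximum (linear interpolation between days); the failure
    time is the first crossing of leaf water potential below the 99%-PLC
    potential of the vulnerability curve.  ``t_cav`` and ``thf`` are nan when
    failure is not reached within the run (flagged, as for dry-downs cut short
    by weather).
    """
    traits = traits if traits is not None else traj.traits
    df = traj.data
    t_h = df["time"].to_numpy(float)
    psi_leaf = df["psi_leaf"].to_numpy(float)
    psi_fail = psi_at_plc(FAILURE_PLC, traits.p50, traits.vc_slope)
    psi_min = float(psi_leaf.min())

    daily = daily_extremes(traj)
    if len(daily) == 0:
        raise ValueError("trajectory too short for daily extremes")
    e_mid = daily["midday_e"].to_numpy(float)
    d_mid = daily["day"].to_numpy(float) + 0.5  # midday sample time in days
    threshold = CLOSURE_E_FRACTION * float(e_mid.max())
    # closure crossing must follow the E maximum (initial ramp-up excluded)
    imax = int(np.argmax(e_mid))
    t_close = _first_crossing(d_mid[imax:], e_mid[imax:], threshold)
    reached_close = not math.isnan(t_close)
    psi_close = (float(np.interp(t_close, d_mid, daily["midday_psi"]))
                 if reached_close else math.nan)

    t_fail = _first_crossing(t_h / 24.0, psi_leaf, psi_fail)
    reached_failure = not math.isnan(t_fail)
    t_cav = t_fail - t_close if (reached_close and reached_failure) else math.nan
    thf = t_fail if (reached_close and reached_failure) else math.nan

    return DehydrationMetrics(
        t_close=t_close, t_cav=t_cav, thf=thf, psi_min=psi_min,
        psi_close=psi_close, psi_fail=psi_fail,
        reached_close=reached_close, reached_failure=reached_failure)


def compare_to_observations(model_daily: pd.DataFrame,
                            observed: pd.DataFrame,
                            psi_close: Optional[float] = None) -> pd.DataFrame:
    """Fit statistics of modelled vs observed predawn/midday water potentials.

    Both frames carry columns day, predawn_psi, midday_psi; rows are matched
    on day.  Returns RMSE (MPa), mean bias (model - observed, MPa) and the
    concordance slope (least-squares through the origin) per variable, overall
    and split into pre-/post-closure phases when ``psi_close`` is given (phase
    assigned by the observed midday potential).
    """
    merged = model_daily.merge(observed, on="day", suffixes=("_mod", "_obs"))
    if len(merged) == 0:
        raise ValueError("no overlapping days between model and observations")

    def stats(mod: np.ndarray, obs: np.ndarray) -> dict:
        mask = np.isfinite(mod) & np.isfinite(obs)
        mod, obs = mod[mask], obs[mask]
        if len(mod) == 0:
            return {"n": 0, "rmse": math.nan, "bias": math.nan, "slope": math.nan}
        denom = float(np.dot(obs, obs))
        return {
            "n": int(len(mod)),
            "rmse": float(np.sqrt(np.mean((mod - obs) ** 2))),
            "bias": float(np.mean(mod - obs)),
            "slope": float(np.dot(mod, obs) / denom) if denom > 0 else math.nan,
        }

    rows = []
    phases: list[tuple[str, np.ndarray]] = [("all", np.ones(len(merged), bool))]
    if psi_close is not None:
        obs_mid = merged["midday_psi_obs"].to_numpy(float)
        phases += [("pre_closure", obs_mid > psi_close),
                   ("post_closure", obs_mid <= psi_close)]
    for var in ("predawn_psi", "midday_psi"):
        mod = merged[f"{var}_mod"].to_numpy(float)
        obs = merged[f"{var}_obs"].to_numpy(float)
        for phase, mask in phases:
            rows.append({"variable": var, "phase": phase,
                         **stats(mod[mask], obs[mask])})
    return pd.DataFrame(rows)
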