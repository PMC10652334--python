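"""Fitters that turn raw dry-down measurements into model traits.

Implements the analysis side of the bench/drought-box/balance protocols:

* midday transpiration from 5-min balance mass series (least-squares slope,
  robust to the 50 g balance quantization),
* the Weibull fit of midday E vs water potential and the P_gs88 closure point,
* pressure-volume analysis (1/psi vs water deficit) for pi0, epsilon and TLP,
* residual conductance from the post-closure linear phase of a drought-box
  mass series,
* the two-segment Arrhenius fit giving the g_res phase-transition temperature
  T_p and the Q10 factors below/above it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .physiology import ATM_PRESSURE_KPA

__all__ = ["ObservationSet", "midday_transpiration_from_mass", "fit_pgs88",
           "fit_pressure_volume", "fit_residual_conductance",
           "fit_temperature_response", "WeibullFit", "PVFit",
           "TemperatureResponseFit", "FitError", "WATER_G_PER_MOL"]

WATER_G_PER_MOL = 18.015


class FitError(RuntimeError):
    pass


@dataclass
class ObservationSet:
    """Observed dry-down records for one tree (or a synthetic emulation).

    ``psi``: columns day, tree_id, predawn_psi, midday_psi (MPa).
    ``mass``: columns time_min, tree_id, mass_g (5-min balance records).
    ``shed``: columns day, tree_id, shed_dry_mass_g (deciduous), or None.
    ``meta``: leaf_area (m2), treatment, and any generator metadata.
    """

    psi: pd.DataFrame
    mass: pd.DataFrame
    shed: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)
    truth: Optional[object] = None  # noise-free SimTrajectory, if synthetic


def midday_transpiration_from_mass(mass: pd.DataFrame, leaf_area: float,
                                   window_h: float = 2.0,
                                   midday_h: float = 13.0) -> pd.DataFrame:
    """Daily midday transpiration (mmol m^-2 s^-1) from a balance mass series.

    For each day the mass records inside the window centred on ``midday_h``
    are fitted with a least-squares line; the (negative) slope normalized by
    leaf area gives E.  The slope over all in-window samples averages out the
    balance quantization.  Days with an apparent mass *gain* beyond one
    quantization step are flagged (watering or disturbance).
    """
    if leaf_area <= 0:
        raise ValueError(f"leaf_area must be > 0, got {leaf_area}")
    t_min = mass["time_min"].to_numpy(float)
    m_g = mass["mass_g"].to_numpy(float)
    quantum = float(mass.attrs.get("mass_quantum", 50.0))
    day = np.floor(t_min / 1440.0).astype(int)
    rows = []
    for d in np.unique(day):
        sel = day == d
        h = t_min[sel] / 60.0 - d * 24.0
        win = (h >= midday_h - window_h / 2.0) & (h <= midday_h + window_h / 2.0)
        if win.sum() < 2:
            continue
        tt = t_min[sel][win] * 60.0  # s
        mm = m_g[sel][win]
        slope_g_s = float(np.polyfit(tt, mm, 1)[0])
        gain = mm[-1] - mm[0]
        flagged = gain > max(quantum, 1e-9)
        e = max(0.0, -slope_g_s) / WATER_G_PER_MOL / leaf_area * 1000.0
        rows.append({"day": int(d), "midday_e": e, "flagged": bool(flagged)})
    if not rows:
        raise FitError("no day had >= 2 mass samples inside the midday window")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WeibullFit:
    e_max: float  # mmol m^-2 s^-1
    b: float  # MPa (tension scale, > 0)
    c: float  # shape (> 0)
    p_gs88: float  # MPa, psi where fitted E = 0.12 * e_max
    rmse: float


def fit_pgs88(points: pd.DataFrame | Sequence[tuple[float, float]],
              threshold: float = 0.12) -> WeibullFit:
    """Fit ``E(psi) = Emax * exp(-((-psi)/b)**c)`` and locate P_gs88.

    ``points`` carries midday psi (MPa, <= 0) and midday E pairs (columns
    midday_psi / midday_e, or 2-tuples).  Nonlinear least squares with a
    multi-start grid on (b, c); the closure point is where the *fitted* curve
    falls to ``threshold * Emax``: ``-b * (-ln(threshold))**(1/c)``.
    """
    if isinstance(points, pd.DataFrame):
        psi = points["midday_psi"].to_numpy(float)
        e = points["midday_e"].to_numpy(float)
    else:
        arr = np.asarray(points, float)
        psi, e = arr[:, 0], arr[:, 1]
    mask = np.isfinite(psi) & np.isfinite(e)
    psi, e = psi[mask], e[mask]
    if len(psi) < 6:
        raise FitError(f"need >= 6 points, got {len(psi)}")
    if np.ptp(e) < 1e-12 * max(1.0, abs(float(e.max()))):
        raise FitError("degenerate data: all E values equal")
    tension = -psi
    if tension.min() < 0:
        raise FitError("water potentials must be <= 0")

    def model(x, emax, b, c):
        return emax * np.exp(-((x / b) ** c))

    e_max0 = float(e.max())
    t_med = float(np.median(tension[tension > 0])) if (tension > 0).any() else 1.0
    best, best_sse = None, math.inf
    for b0 in (0.5 * t_med, t_med, 2.0 * t_med):
        for c0 in (1.0, 2.0, 4.0, 8.0):
            try:
                popt, _ = curve_fit(model, tension, e, p0=[e_max0, b0, c0],
                                    bounds=([1e-9, 1e-6, 0.05],
                                            [np.inf, np.inf, 50.0]),
                                    maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((model(tension, *popt) - e) ** 2))
            if sse < best_sse:
                best, best_sse = popt, sse
    if best is None:
        raise FitError("Weibull fit failed to converge from every start")
    emax, b, c = (float(v) for v in best)
    p_gs88 = -b * (-math.log(threshold)) ** (1.0 / c)
    rmse = math.sqrt(best_sse / len(e))
    return WeibullFit(e_max=emax, b=b, c=c, p_gs88=p_gs88, rmse=rmse)


@dataclass(frozen=True)
class PVFit:
    pi0: float  # MPa
    epsilon: float  # MPa
    tlp: float  # MPa
    split_index: int  # first point of the post-TLP (linear) segment
    r2_tail: float


def fit_pressure_volume(curve: pd.DataFrame | Sequence[tuple[float, float]]) -> PVFit:
    """Standard pressure-volume analysis on (RWC, psi) bench-dehydration data.

    Points are sorted by decreasing RWC; on 1/psi vs (1 - RWC) axes the
    post-turgor-loss segment is linear with intercept 1/pi0.  The segment
    split is chosen by maximizing the linearity (r^2) of the tail fit;
    epsilon comes from the slope of turgor (psi - osmotic) against water
    deficit on the pre-TLP points, and the TLP from pi0/(1 + pi0/epsilon).
    """
    if isinstance(curve, pd.DataFrame):
        rwc = curve["rwc"].to_numpy(float)
        psi = curve["psi"].to_numpy(float)
    else:
        arr = np.asarray(curve, float)
        rwc, psi = arr[:, 0], arr[:, 1]
    if len(rwc) < 8:
        raise FitError(f"need >= 8 points, got {len(rwc)}")
    order = np.argsort(-rwc)
    rwc, psi = rwc[order], psi[order]
    if (psi >= 0).any():
        raise FitError("all psi must be < 0 for PV analysis")
    x = 1.0 - rwc  # water deficit
    inv_psi = 1.0 / psi

    n = len(x)
    best = None
    for split in range(2, n - 2):  # tail = points[split:], >= 3 points
        if n - split < 3:
            break
        xs, ys = x[split:], inv_psi[split:]
        sl, ic = np.polyfit(xs, ys, 1)
        pred = sl * xs + ic
        ss_res = float(np.sum((ys - pred) ** 2))
        ss_tot = float(np.sum((ys - ys.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -math.inf
        if best is None or r2 > best[0]:
            best = (r2, split, sl, ic)
    if best is None:
        raise FitError("no linear tail detectable")
    r2, split, sl, ic = best
    if ic >= 0:
        raise FitError("post-TLP intercept implies non-negative pi0")
    pi0 = 1.0 / ic

    # pre-TLP turgor from the extrapolated osmotic line: pi(x) = 1/(sl*x + ic)
    xh, psih = x[:split], psi[:split]
    osmotic = 1.0 / (sl * xh + ic)
    turgor = psih - osmotic
    if len(xh) < 2:
        raise FitError("too few pre-TLP points for the elasticity fit")
    eps_slope = np.polyfit(xh, turgor, 1)[0]
    epsilon = float(-eps_slope)
    if epsilon <= 0:
        raise FitError("pre-TLP turgor slope implies non-positive epsilon")
    tlp = pi0 / (1.0 + pi0 / epsilon)
    return PVFit(pi0=float(pi0), epsilon=epsilon, tlp=float(tlp),
                 split_index=int(split), r2_tail=float(r2))


def fit_residual_conductance(mass: pd.DataFrame, t_air: float, rh: float,
                             area_m2: float,
                             atm_pressure: float = ATM_PRESSURE_KPA,
                             stability: float = 0.10) -> float:
    """Residual conductance (mmol m^-2 s^-1) from a drought-box mass series.

    ``mass`` has columns time_min, mass_g for one branch dehydrating under
    constant (t_air, rh).  The post-stomatal-closure phase is detected as the
    longest terminal window whose local mass-loss slope stays within
    ``stability`` (relative) of the terminal slope; g_res is that slope
    normalized by VPD/Patm and the evaporating area (double-sided LA + stem
    for broadleaves, projected LA + stem for conifers — the caller supplies
    the convention through ``area_m2``).
    """
    from .physiology import vapour_pressure_deficit

    if area_m2 <= 0:
        raise ValueError(f"area_m2 must be > 0, got {area_m2}")
    vpd = vapour_pressure_deficit(t_air, rh)
    if vpd <= 0:
        raise FitError("VPD is zero: residual conductance undefined")
    t_s = mass["time_min"].to_numpy(float) * 60.0
    m_g = mass["mass_g"].to_numpy(float)
    n = len(t_s)
    if n < 6:
        raise FitError(f"need >= 6 mass samples, got {n}")

    # terminal reference slope over the last quarter of the series
    i_ref = max(n - max(n // 4, 3), 0)
    ref_slope = float(np.polyfit(t_s[i_ref:], m_g[i_ref:], 1)[0])
    if ref_slope >= 0:
        raise FitError("terminal phase shows no mass loss")

    # extend the window backwards while the local slope stays stable
    start = i_ref
    chunk = max(n // 20, 2)
    while start - chunk >= 0:
        local = float(np.polyfit(t_s[start - chunk:start + 1],
                                 m_g[start - chunk:start + 1], 1)[0])
        if abs(local - ref_slope) > stability * abs(ref_slope):
            break
        start -= chunk
    slope = float(np.polyfit(t_s[start:], m_g[start:], 1)[0])
    loss_mmol_s = -slope / WATER_G_PER_MOL * 1000.0
    return loss_mmol_s / (vpd / atm_pressure) / area_m2


@dataclass(frozen=True)
class TemperatureResponseFit:
    t_p: float  # degC
    q10_a: float
    q10_b: float
    degenerate: bool  # single-slope data: t_p indeterminate


def fit_temperature_response(points: pd.DataFrame | Sequence[tuple[float, float]]
                             ) -> TemperatureResponseFit:
    """Two-segment Arrhenius fit of g_res vs temperature.

    The breakpoint T_p is found by exhaustive search over interior splits of
    ln(g_res) vs 1/T(K), minimizing the combined SSE of the two line fits
    (>= 2 points per side); T_p is the intersection of the two Arrhenius
    lines.  The Q10 factors are then taken from the slope of ln(g_res) vs
    T (degC) within each segment, ``Q10 = exp(10 * slope)`` — the Q10 of the
    g-vs-temperature relationship on each side of T_p.
    """
    if isinstance(points, pd.DataFrame):
        t_c = points["t_air"].to_numpy(float)
        g = points["g_res"].to_numpy(float)
    else:
        arr = np.asarray(points, float)
        t_c, g = arr[:, 0], arr[:, 1]
    if len(t_c) < 5:
        raise FitError(f"need >= 5 temperature levels, got {len(t_c)}")
    if (g <= 0).any():
        raise FitError("g_res values must be > 0")
    order = np.argsort(t_c)
    t_c, g = t_c[order], g[order]
    ln_g = np.log(g)
    inv_tk = 1.0 / (t_c + 273.15)

    n = len(t_c)
    best = None
    for split in range(2, n - 1):  # low side [0:split], high side [split:]
        lo_sl, lo_ic = np.polyfit(inv_tk[:split], ln_g[:split], 1)
        hi_sl, hi_ic = np.polyfit(inv_tk[split:], ln_g[split:], 1)
        sse = (float(np.sum((lo_sl * inv_tk[:split] + lo_ic - ln_g[:split]) ** 2))
               + float(np.sum((hi_sl * inv_tk[split:] + hi_ic - ln_g[split:]) ** 2)))
        if best is None or sse < best[0]:
            best = (sse, split, lo_sl, lo_ic, hi_sl, hi_ic)
    sse, split, lo_sl, lo_ic, hi_sl, hi_ic = best

    q10_a = float(math.exp(10.0 * np.polyfit(t_c[:split], ln_g[:split], 1)[0]))
    q10_b = float(math.exp(10.0 * np.polyfit(t_c[split:], ln_g[split:], 1)[0]))

    # single-slope data: the segment Q10s coincide and no breakpoint exists
    if (abs(hi_sl - lo_sl) < 1e-9 * max(abs(hi_sl), abs(lo_sl), 1.0)
            or abs(q10_a - q10_b) < 5e-3 * max(q10_a, q10_b)):
        return TemperatureResponseFit(t_p=math.nan, q10_a=q10_a, q10_b=q10_b,
                                      degenerate=True)
    inv_tp = (lo_ic - hi_ic) / (hi_sl - lo_sl)
    if inv_tp <= 0:
        # lines intersect outside the physical range; fall back to the gap
        # midpoint between the two segments
        t_p = float(0.5 * (t_c[split - 1] + t_c[split]))
        degenerate = True
    else:
        t_p = float(1.0 / inv_tp - 273.15)
        degenerate = False
        # close-to-parallel fits can throw the intersection far outside the
        # sampled range; clamp to the gap midpoint in that case
        if not (t_c[0] - 10.0 <= t_p <= t_c[-1] + 10.0):
            t_p = float(0.5 * (t_c[split - 1] + t_c[split]))
    return TemperatureResponseFit(t_p=t_p, q10_a=q10_a, q10_b=q10_b,
                                  degenerate=degenerate)
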