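"""Physiological response curves.

Pure functions for the water relations that drive the dehydration simulator:

* symplast pressure-volume relations (osmotic + turgor components),
* the sigmoidal xylem vulnerability curve (PLC vs water potential) and its
  analytic inverse,
* stomatal conductance regulated by bulk leaf turgor with a binary light
  factor,
* temperature response of the residual (cuticular + leaky-stomata) branch
  conductance with a phase transition at ``t_p``,
* bark conductance (twice the residual branch conductance),
* the deciduous leaf-shedding sigmoid,
* Tetens vapour pressure deficit.

All potentials are in MPa (<= 0 in plants), conductances in mmol m^-2 s^-1,
temperatures in degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .traits import SheddingParams, SpeciesTraits

__all__ = [
    "PVState",
    "symplast_water_potential",
    "relative_content_at_psi",
    "turgor_at_psi",
    "plc_at_psi",
    "psi_at_plc",
    "stomatal_conductance",
    "residual_conductance_at_T",
    "bark_conductance",
    "leaf_shedding_fraction",
    "vapour_pressure_deficit",
    "PAR_LIGHT_THRESHOLD",
    "ATM_PRESSURE_KPA",
]

#: PAR (umol m^-2 s^-1) above which stomata may open (binary light factor).
PAR_LIGHT_THRESHOLD = 10.0
#: Default atmospheric pressure (kPa); site elevation ~350 m folded into config.
ATM_PRESSURE_KPA = 101.3


@dataclass(frozen=True)
class PVState:
    """Symplast water status at a given relative water content."""

    psi_total: float  # MPa
    osmotic: float  # MPa
    turgor: float  # MPa, >= 0
    r_symplast: float  # relative symplast water content in (0, 1]


def symplast_water_potential(r: float, pi0: float, epsilon: float) -> PVState:
    """Symplast water potential from the two-parameter pressure-volume model.

    The osmotic component concentrates as the symplast loses water
    (``pi0 / r``) and the turgor component declines linearly with relative
    water deficit (``-pi0 - epsilon * (1 - r)``, floored at zero).  Turgor
    vanishes at the relative content ``r_tlp = 1 + pi0/epsilon``.

    Parameters
    ----------
    r : relative symplast water content, 0 < r <= 1
    pi0 : osmotic potential at full turgor, MPa (< 0)
    epsilon : bulk modulus of elasticity, MPa (> 0)
    """
    if not (0.0 < r <= 1.0):
        raise ValueError(f"relative water content must be in (0, 1], got {r}")
    if pi0 >= 0:
        raise ValueError(f"pi0 must be < 0, got {pi0}")
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    osmotic = pi0 / r
    turgor = max(0.0, -pi0 - epsilon * (1.0 - r))
    return PVState(psi_total=osmotic + turgor, osmotic=osmotic, turgor=turgor,
                   r_symplast=r)


def relative_content_at_psi(psi: float, pi0: float, epsilon: float) -> float:
    """Invert :func:`symplast_water_potential`: relative content at ``psi`` (<= 0).

    Above the turgor-loss point the inversion solves the quadratic
    ``epsilon*r^2 - (pi0 + epsilon + psi)*r + pi0 = 0`` (the root continuous
    with r=1 at psi=0); below it the relation is purely osmotic, r = pi0/psi.
    """
    if psi > 0:
        raise ValueError(f"psi must be <= 0, got {psi}")
    r_tlp = 1.0 + pi0 / epsilon
    psi_tlp = pi0 / r_tlp if r_tlp > 0 else -math.inf
    if psi <= psi_tlp:
        return pi0 / psi if psi < 0 else 1.0
    b = pi0 + epsilon + psi
    r = (b + math.sqrt(b * b - 4.0 * epsilon * pi0)) / (2.0 * epsilon)
    return min(r, 1.0)


def turgor_at_psi(psi: float, pi0: float, epsilon: float) -> float:
    """Bulk turgor pressure (MPa, >= 0) at total water potential ``psi``."""
    r = relative_content_at_psi(psi, pi0, epsilon)
    return max(0.0, -pi0 - epsilon * (1.0 - r))


def plc_at_psi(psi: float, p50: float, vc_slope: float) -> float:
    """Percent loss of xylem conductivity at water potential ``psi``.

    Sigmoidal (Pammenter-type) vulnerability curve
    ``PLC = 100 / (1 + exp((vc_slope/25) * (psi - p50)))`` whose derivative
    magnitude at ``psi = p50`` equals ``vc_slope`` (% MPa^-1).
    """
    if vc_slope <= 0:
        raise ValueError(f"vc_slope must be > 0, got {vc_slope}")
    x = (vc_slope / 25.0) * (psi - p50)
    if x > 700.0:  # guard exp overflow deep in the saturated tail
        return 0.0
    return 100.0 / (1.0 + math.exp(x))


def psi_at_plc(plc: float, p50: float, vc_slope: float) -> float:
    """Analytic inverse of :func:`plc_at_psi` for PLC strictly in (0, 100)."""
    if not (0.0 < plc < 100.0):
        raise ValueError(f"plc must be in (0, 100), got {plc}")
    if vc_slope <= 0:
        raise ValueError(f"vc_slope must be > 0, got {vc_slope}")
    return p50 + (25.0 / vc_slope) * math.log(100.0 / plc - 1.0)


def stomatal_conductance(psi_leaf: float, traits: "SpeciesTraits",
                         par: float) -> float:
    """Stomatal conductance (mmol m^-2 s^-1) at leaf water potential ``psi_leaf``.

    Stomata respond to bulk leaf turgor: gs is gs_max scaled by turgor relative
    to its full-hydration value (-pi0), so closure emerges exactly at the
    derived turgor-loss point.  A binary light factor shuts stomata when PAR is
    below :data:`PAR_LIGHT_THRESHOLD` (night).
    """
    if psi_leaf > 0:
        raise ValueError(f"psi_leaf must be <= 0, got {psi_leaf}")
    if par < 0:
        raise ValueError(f"par must be >= 0, got {par}")
    if par < PAR_LIGHT_THRESHOLD:
        return 0.0
    rel_turgor = turgor_at_psi(psi_leaf, traits.pi0, traits.epsilon) / (-traits.pi0)
    return traits.gs_max * min(1.0, max(0.0, rel_turgor))


def residual_conductance_at_T(t_air: float, traits: "SpeciesTraits") -> float:
    """Residual branch conductance (mmol m^-2 s^-1) at air temperature ``t_air``.

    Q10 response with a phase transition at ``t_p``:
    ``g(T) = g_res * q10_a**((T - 25)/10)`` for T <= t_p, then continues from
    ``g(t_p)`` with ``q10_b`` above.  Continuous at ``t_p`` by construction.
    """
    from .traits import GRES_REFERENCE_T

    if not (-20.0 <= t_air <= 60.0):
        raise ValueError(f"t_air outside supported range [-20, 60]: {t_air}")
    if t_air <= traits.t_p:
        return traits.g_res * traits.q10_a ** ((t_air - GRES_REFERENCE_T) / 10.0)
    g_tp = traits.g_res * traits.q10_a ** ((traits.t_p - GRES_REFERENCE_T) / 10.0)
    return g_tp * traits.q10_b ** ((t_air - traits.t_p) / 10.0)


def bark_conductance(traits: "SpeciesTraits") -> float:
    """Bark conductance per unit bark surface: double the residual conductance."""
    return 2.0 * traits.g_res


def leaf_shedding_fraction(psi_leaf: float,
                           shedding_params: Optional["SheddingParams"]) -> float:
    """Percentage of initial leaf area shed at leaf water potential ``psi_leaf``.

    Sigmoid ``PLF = 100 / (1 + exp(rate * (psi_leaf - psi_half)))``; returns 0
    for species without a shedding response (``shedding_params is None``).
    The *applied* canopy loss along a trajectory is the running maximum of
    this value (shedding is irreversible); that bookkeeping lives in the
    simulator.
    """
    if psi_leaf > 0:
        raise ValueError(f"psi_leaf must be <= 0, got {psi_leaf}")
    if shedding_params is None:
        return 0.0
    x = shedding_params.rate * (psi_leaf - shedding_params.psi_half)
    if x > 700.0:
        return 0.0
    return 100.0 / (1.0 + math.exp(x))


def vapour_pressure_deficit(t_air: float, rh: float) -> float:
    """Vapour pressure deficit (kPa) from air temperature (degC) and RH (%).

    Tetens saturation vapour pressure:
    ``es(T) = 0.61078 * exp(17.27*T / (T + 237.3))`` kPa.
    """
    if not (0.0 <= rh <= 100.0):
        raise ValueError(f"rh must be in [0, 100], got {rh}")
    es = 0.61078 * math.exp(17.27 * t_air / (t_air + 237.3))
    return es * (1.0 - rh / 100.0)
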