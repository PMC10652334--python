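"""Compartment dehydration simulator.

Time-steps the soil-root-trunk-branch-leaf network from full hydration to
hydraulic failure under hourly climate forcing.  Water moves between
compartments down water-potential gradients through axial conductances scaled
by the cavitation state (1 - PLC/100); canopy transpiration follows
``E = gs * VPD / Patm`` over the remaining leaf area, with residual (leaf)
and bark losses continuing day and night; symplast pools set compartment
water potentials through the pressure-volume curve; apoplast pools discharge
water in proportion to the increase in PLC (capacitive release once
cavitation begins); PLC and the deciduous shed fraction are running maxima
(no refilling, no regrowth).

Numerics: backward-Euler on the four plant pools solved simultaneously by
damped Newton with a tridiagonal Jacobian (chain topology), with adaptive
sub-stepping — leaf symplast time constants are tens of seconds, far below
the 600 s default step, so explicit stepping would be unstable.  Soil state
and cavitation-scaled conductances are frozen over each sub-step; a sweep
that fails to converge halves the step.  Internal fluxes are evaluated once
at the converged state and applied antisymmetrically, so water is conserved
to floating-point rounding.  The flat numerical core lives in
:mod:`drydown._kernel` and is JIT-compiled when numba is available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .architecture import (MOL_PER_L, DEFAULT_K_PLANT, PlantNetwork,
                           SoilParams, build_fractal_tree)
from .climate import ClimateSeries
from .physiology import ATM_PRESSURE_KPA, PAR_LIGHT_THRESHOLD
from .traits import GRES_REFERENCE_T, SpeciesTraits

__all__ = ["SimOptions", "SimTrajectory", "run_dehydration",
           "simulate_species_panel", "SimulationError",
           "STANDARD_LEAF_AREA", "STANDARD_POT_VOLUME"]

#: Common canopy size (m2) for standardized species panels and sensitivity runs.
STANDARD_LEAF_AREA = 2.0
#: Common pot volume (L) for standardized species panels and sensitivity runs.
STANDARD_POT_VOLUME = 20.0


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimOptions:
    dt_max: float = 600.0  # s
    dt_min: float = 1.0  # s
    mass_balance_tol: float = 1e-3  # fraction of initial water per simulated day
    stop_plc: float = 99.0  # % leaf PLC at which the run terminates
    max_days: Optional[int] = None  # default: full climate duration
    #: Initial soil relative water content (%).  None starts at field
    #: capacity: the model has no drainage flux, and in a freshly watered pot
    #: the water above field capacity drains gravitationally rather than
    #: passing through the plant.  Set to ``soil.rwc_sat`` explicitly to
    #: start from a fully saturated, undrained profile.
    initial_rwc: Optional[float] = None
    atm_pressure: float = ATM_PRESSURE_KPA  # kPa

    def __post_init__(self) -> None:
        if not (0.0 < self.dt_min <= self.dt_max):
            raise ValueError("require 0 < dt_min <= dt_max")
        if not (0.0 < self.stop_plc < 100.0):
            raise ValueError("stop_plc must be in (0, 100)")


@dataclass
class SimTrajectory:
    """Hourly output of one dehydration run plus run metadata."""

    data: pd.DataFrame
    traits: SpeciesTraits
    options: SimOptions
    soil: SoilParams
    initial_water_mol: float
    mass_balance_error: float  # |residual| as fraction of initial water
    failed: bool  # reached stop_plc (hydraulic failure)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def duration_days(self) -> float:
        return float(self.data["time"].iloc[-1]) / 24.0


def run_dehydration(traits: SpeciesTraits, network: PlantNetwork,
                    soil: SoilParams, climate: ClimateSeries,
                    options: SimOptions = SimOptions()) -> SimTrajectory:
    """Run one dry-down from (near) full hydration to hydraulic failure.

    Returns the hourly :class:`SimTrajectory`; the run stops when leaf PLC
    reaches ``options.stop_plc`` or the climate/``max_days`` horizon is
    reached.
    """
    from ._kernel import simulate_core
    from .architecture import PSI_SOIL_CLIP

    time_h, t_air_arr, _rh, par_arr, _wind, vpd_arr = climate.arrays()
    n_hours = len(time_h)
    if options.max_days is not None:
        horizon_h = options.max_days * 24
        if horizon_h > time_h[-1] - time_h[0] + 1e-9:
            raise SimulationError(
                f"climate covers {climate.duration_days:.1f} days but "
                f"max_days={options.max_days} requested")
        n_hours = min(n_hours, int(round(horizon_h - time_h[0])) + 1)

    theta0 = options.initial_rwc if options.initial_rwc is not None else soil.rwc_fc
    if not (soil.rwc_res < theta0 <= soil.rwc_sat):
        raise SimulationError(f"initial_rwc {theta0} outside (rwc_res, rwc_sat]")

    comps = network.compartments
    w_sat = np.array([c.symplast_capacity_mol for c in comps])
    apo_cap = np.array([c.apoplast_capacity_mol for c in comps])
    bark_area = np.array([c.surface_area_m2 for c in comps])
    k_ax = np.array([c.k_axial for c in comps])
    shed = traits.shedding_params if traits.deciduous else None

    (status, fail_time, nrow, out_time, out_psi_soil, out_psi, out_gs,
     out_e_sto, out_e_res, out_plc_leaf, out_plc_stem, out_theta, out_la,
     out_loss, w_init_total, w_now_total, cum_loss) = simulate_core(
        time_h[:n_hours], t_air_arr[:n_hours], vpd_arr[:n_hours],
        par_arr[:n_hours],
        traits.pi0, traits.epsilon, traits.p50, traits.vc_slope,
        traits.gs_max, traits.g_res, traits.q10_a, traits.q10_b, traits.t_p,
        traits.leaf_surface_ratio,
        shed is not None,
        shed.rate if shed is not None else 0.0,
        shed.psi_half if shed is not None else 0.0,
        w_sat, apo_cap, bark_area, k_ax, network.leaf_area,
        soil.pot_volume, soil.rwc_sat, soil.rwc_res, soil.b_retention,
        soil.psi_e, soil.k_sat_soilroot,
        options.dt_max, options.dt_min, options.stop_plc, theta0,
        options.atm_pressure, GRES_REFERENCE_T, PAR_LIGHT_THRESHOLD,
        PSI_SOIL_CLIP, MOL_PER_L)

    if status == 2:
        raise SimulationError(
            f"sub-step failed to converge at t={fail_time:.2f} h even at "
            f"dt_min={options.dt_min} s")
    failed = status == 1

    sl = slice(0, nrow)
    df = pd.DataFrame({
        "time": out_time[sl], "psi_soil": out_psi_soil[sl],
        "psi_root": out_psi[sl, 0], "psi_trunk": out_psi[sl, 1],
        "psi_branch": out_psi[sl, 2], "psi_leaf": out_psi[sl, 3],
        "gs": out_gs[sl], "e_canopy": out_e_sto[sl],
        "e_residual": out_e_res[sl], "plc_leaf": out_plc_leaf[sl],
        "plc_stem": out_plc_stem[sl], "theta_rel": out_theta[sl],
        "leaf_area": out_la[sl], "cum_loss": out_loss[sl]})
    df["closed_stomata"] = df["gs"] <= 1e-6 * traits.gs_max
    df["failed"] = False
    if failed:
        df.loc[df.index[-1], "failed"] = True

    residual = abs(w_init_total - w_now_total - cum_loss)
    mbe = residual / w_init_total
    days = max(float(df["time"].iloc[-1] - df["time"].iloc[0]) / 24.0, 1e-9)
    if mbe > options.mass_balance_tol * days:
        raise SimulationError(
            f"mass balance violated: residual {mbe:.2e} of initial water over "
            f"{days:.1f} days (tol {options.mass_balance_tol}/day)")

    return SimTrajectory(data=df, traits=traits, options=options, soil=soil,
                         initial_water_mol=w_init_total,
                         mass_balance_error=mbe, failed=failed)


def simulate_species_panel(trait_set: list[SpeciesTraits], standardized: bool,
                           climate: ClimateSeries,
                           options: SimOptions = SimOptions(),
                           soil: Optional[SoilParams] = None,
                           k_plant: float = DEFAULT_K_PLANT,
                           std_leaf_area: float = STANDARD_LEAF_AREA,
                           std_pot_volume: float = STANDARD_POT_VOLUME,
                           ) -> list[SimTrajectory]:
    """Dry down several species under one climate.

    With ``standardized=True`` every species gets the common leaf area and pot
    volume before the networks are built (the protocol for comparing species
    THF); otherwise each species keeps its own allometry and the supplied (or
    default) soil.
    """
    soil = soil if soil is not None else SoilParams()
    out = []
    for traits in trait_set:
        tr = traits
        s = soil
        if standardized:
            tr = traits.perturbed(leaf_area=std_leaf_area)
            s = replace(soil, pot_volume=std_pot_volume)
        net = build_fractal_tree(tr, k_plant=k_plant)
        out.append(run_dehydration(tr, net, s, climate, options))
    return out
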