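"""Synthetic "observed" pot dry-down datasets.

Emulates the experimental data stream of a balance-monitored pot drought:
5-min pot-mass records quantized at the balance resolution (50 g), predawn
and midday xylem water potentials every few days with additive Gaussian
noise, and daily shed-leaf dry-mass records for deciduous species.  The
generator runs the dehydration simulator for the noise-free truth (kept on
the returned :class:`~drydown.trait_extraction.ObservationSet` for recovery
tests) and is fully reproducible from its seed.

Not emulated: watering events (dry-down only), soil evaporation (pots are
film-covered) and embolism imaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .architecture import MOL_PER_L, SoilParams, build_fractal_tree
from .climate import ClimateSeries
from .metrics import daily_extremes, dehydration_times
from .simulator import SimOptions, SimTrajectory, run_dehydration
from .trait_extraction import WATER_G_PER_MOL, ObservationSet
from .traits import SpeciesTraits

__all__ = ["generate_observed_dataset", "DEFAULT_PSI_SD", "DEFAULT_MASS_QUANTUM"]

DEFAULT_PSI_SD = 0.15  # MPa
DEFAULT_MASS_QUANTUM = 50.0  # g
DEFAULT_TARE_G = 5000.0  # pot + dry soil + hardware, constant
LEAF_DRY_MASS_PER_AREA = 80.0  # g m^-2, for shed-leaf records


def generate_observed_dataset(traits: SpeciesTraits, climate: ClimateSeries,
                              psi_sd: float = DEFAULT_PSI_SD,
                              mass_quantum: float = DEFAULT_MASS_QUANTUM,
                              psi_every_days: int = 3,
                              mass_every_min: float = 5.0,
                              seed: int = 0,
                              soil: Optional[SoilParams] = None,
                              options: Optional[SimOptions] = None,
                              heteroscedastic: bool = False,
                              tree_id: str = "synthetic-1") -> ObservationSet:
    """Simulate one tree's dry-down and emit its noisy observation records.

    With ``psi_sd = 0`` and ``mass_quantum = 0`` the records equal the
    noise-free truth exactly.  ``heteroscedastic=True`` doubles the water
    potential noise once the tree passes stomatal closure (variability rises
    near peak stress in strongly shedding species); off by default.
    """
    soil = soil if soil is not None else SoilParams()
    options = options if options is not None else SimOptions()
    rng = np.random.default_rng(seed)

    network = build_fractal_tree(traits)
    traj = run_dehydration(traits, network, soil, climate, options)
    daily = daily_extremes(traj)

    # --- water potential records -----------------------------------------
    psi_days = daily[daily["day"] % psi_every_days == 0].reset_index(drop=True)
    sd = np.full(len(psi_days), float(psi_sd))
    if heteroscedastic and psi_sd > 0:
        m = dehydration_times(traj, traits)
        psi_close = m.psi_close if m.reached_close else traits.turgor_loss_point
        sd = np.where(psi_days["midday_psi"] < psi_close, 2.0 * psi_sd, psi_sd)
    psi_obs = pd.DataFrame({
        "day": psi_days["day"],
        "tree_id": tree_id,
        "predawn_psi": psi_days["predawn_psi"] + rng.normal(0.0, 1.0, len(psi_days)) * sd,
        "midday_psi": psi_days["midday_psi"] + rng.normal(0.0, 1.0, len(psi_days)) * sd,
    })

    # --- balance mass records --------------------------------------------
    t_h = traj.data["time"].to_numpy(float)
    cum_loss = traj.data["cum_loss"].to_numpy(float)  # mol
    t_min = np.arange(t_h[0] * 60.0, t_h[-1] * 60.0 + 1e-9, mass_every_min)
    loss_5min = np.interp(t_min / 60.0, t_h, cum_loss)
    water_g = (traj.initial_water_mol - loss_5min) * WATER_G_PER_MOL
    mass_g = DEFAULT_TARE_G + water_g
    if mass_quantum > 0:
        mass_g = np.round(mass_g / mass_quantum) * mass_quantum
    mass = pd.DataFrame({"time_min": t_min, "tree_id": tree_id, "mass_g": mass_g})
    mass.attrs["mass_quantum"] = float(mass_quantum)

    # --- shed-leaf records (deciduous) ------------------------------------
    shed = None
    if traits.deciduous:
        la = traj.data["leaf_area"].to_numpy(float)
        day_idx = np.floor(t_h / 24.0).astype(int)
        rows = []
        prev = la[0]
        for d in np.unique(day_idx):
            la_end = float(la[day_idx == d][-1])
            shed_m2 = max(0.0, prev - la_end)
            rows.append({"day": int(d), "tree_id": tree_id,
                         "shed_dry_mass_g": shed_m2 * LEAF_DRY_MASS_PER_AREA})
            prev = la_end
        shed = pd.DataFrame(rows)

    meta = {"leaf_area": traits.leaf_area, "treatment": "WS",
            "species_id": traits.species_id, "seed": int(seed),
            "psi_sd": float(psi_sd), "mass_quantum": float(mass_quantum),
            "tare_g": DEFAULT_TARE_G}
    return ObservationSet(psi=psi_obs, mass=mass, shed=shed, meta=meta,
                          truth=traj)
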