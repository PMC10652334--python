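"""Shared fixtures.

Heavy artefacts (the standardized four-species panel and the N=128 Sobol
analyses) are session-scoped so the qualitative acceptance checks and the
module property tests share one computation.
"""

from __future__ import annotations

import warnings

import pytest
from hypothesis import settings

import drydown as dd

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

SPECIES_IDS = ("Pin_hale", "Pop_nigr", "Que_ilex", "Ced_atla")
EVERGREEN_IDS = ("Pin_hale", "Que_ilex", "Ced_atla")
CONIFER_IDS = ("Pin_hale", "Ced_atla")
ANGIOSPERM_IDS = ("Pop_nigr", "Que_ilex")


@pytest.fixture(scope="session")
def all_traits() -> dict[str, dd.SpeciesTraits]:
    return {sid: dd.load_species_traits(sid) for sid in SPECIES_IDS}


@pytest.fixture(scope="session")
def summer_climate() -> dd.ClimateSeries:
    return dd.synthesize_climate(days=151)


@pytest.fixture(scope="session")
def panel_trajectories(all_traits, summer_climate) -> dict[str, dd.SimTrajectory]:
    """Standardized-LA/pot dry-downs of all four species, default options."""
    opts = dd.SimOptions(max_days=150)
    trajs = dd.simulate_species_panel(list(all_traits.values()),
                                      standardized=True,
                                      climate=summer_climate, options=opts)
    return dict(zip(all_traits.keys(), trajs))


@pytest.fixture(scope="session")
def panel_metrics(panel_trajectories) -> dict[str, dd.DehydrationMetrics]:
    return {sid: dd.dehydration_times(traj)
            for sid, traj in panel_trajectories.items()}


@pytest.fixture(scope="session")
def pin_default_run(summer_climate) -> dd.SimTrajectory:
    """P. halepensis with its own (trait-table) allometry and a 100 L pot."""
    traits = dd.load_species_traits("Pin_hale")
    net = dd.build_fractal_tree(traits)
    soil = dd.SoilParams(pot_volume=100.0)
    return dd.run_dehydration(traits, net, soil, summer_climate,
                              dd.SimOptions(max_days=150))


@pytest.fixture(scope="session")
def sobol_results_128(all_traits) -> dict[str, dict[str, dd.SobolResult]]:
    """N=128 Sobol total-order analyses for every fixture (seeded)."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sid, traits in all_traits.items():
            out[sid] = dd.run_sensitivity(traits, n=128, seed=42)
    return out
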