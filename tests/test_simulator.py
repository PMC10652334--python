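"""Dehydration simulator: equilibrium, closed forms, conservation, dynamics."""

import numpy as np
import pandas as pd
import pytest

import drydown as dd
from drydown.architecture import MOL_PER_L
from drydown.traits import GRES_REFERENCE_T


def constant_climate(days, t_air=25.0, rh=50.0, par=0.0, wind=1.0):
    hours = np.arange(days * 24 + 1, dtype=float)
    return dd.ClimateSeries(pd.DataFrame({
        "time": hours, "t_air": t_air, "rh": rh, "par": par, "wind": wind}))


class TestEquilibrium:
    def test_zero_vpd_dark_equilibrates_to_soil(self, all_traits):
        """Saturated dark air: no losses, all compartments relax to soil psi."""
        t = all_traits["Pin_hale"]
        clim = constant_climate(2, rh=100.0, par=0.0)
        soil = dd.SoilParams(pot_volume=50.0)
        traj = dd.run_dehydration(t, dd.build_fractal_tree(t), soil, clim,
                                  dd.SimOptions(max_days=2))
        last = traj.data.iloc[-1]
        psi_soil = last["psi_soil"]
        for col in ("psi_root", "psi_trunk", "psi_branch", "psi_leaf"):
            assert last[col] == pytest.approx(psi_soil, abs=1e-3)
        assert last["cum_loss"] == pytest.approx(0.0, abs=1e-9)
        assert traj.mass_balance_error < 1e-9


class TestSingleCapacitorClosedForm:
    def test_constant_efflux_linear_decline(self, all_traits):
        """With stomata dark-shut, no bark and no soil link, the plant drains
        at the constant rate g_res * VPD/Patm * LA: cumulative loss follows
        the closed-form line to < 1e-3 relative error."""
        t = all_traits["Pin_hale"]
        clim = constant_climate(2, t_air=25.0, rh=50.0, par=0.0)
        net = dd.build_fractal_tree(t)
        for c in net.compartments:
            c.surface_area_m2 = 0.0  # no bark surface
            c.k_axial = 1e6  # lump the pools into one capacitor
        soil = dd.SoilParams(pot_volume=50.0, k_sat_soilroot=0.0)
        opts = dd.SimOptions(max_days=2)
        traj = dd.run_dehydration(t, net, soil, clim, opts)
        vpd = dd.vapour_pressure_deficit(25.0, 50.0)
        rate_mol_s = t.g_res * (vpd / opts.atm_pressure) * t.leaf_area * 1e-3
        d = traj.data
        expected = rate_mol_s * (d["time"] - d["time"].iloc[0]) * 3600.0
        final = expected.iloc[-1]
        assert final > 0
        assert np.max(np.abs(d["cum_loss"] - expected)) / final < 1e-3
        # soil disconnected: theta untouched
        assert d["theta_rel"].iloc[-1] == pytest.approx(d["theta_rel"].iloc[0])


class TestFullRuns:
    def test_stop_rule_and_terminal_potential(self, panel_trajectories,
                                              all_traits):
        """Runs terminate once leaf PLC passes 99%, with the terminal leaf
        potential at or below the 99%-PLC potential."""
        for sid, traj in panel_trajectories.items():
            t = all_traits[sid]
            assert traj.failed
            last = traj.data.iloc[-1]
            assert last["plc_leaf"] >= 99.0
            assert last["psi_leaf"] <= dd.psi_at_plc(99.0, t.p50, t.vc_slope) + 1e-6

    def test_mass_conservation(self, panel_trajectories, pin_default_run):
        for traj in [*panel_trajectories.values(), pin_default_run]:
            assert traj.mass_balance_error <= 1e-3 * traj.duration_days

    def test_monotone_state_series(self, panel_trajectories):
        """PLC non-decreasing, soil water non-increasing, canopy
        non-increasing, psi <= 0 throughout."""
        for traj in panel_trajectories.values():
            d = traj.data
            assert (np.diff(d["plc_leaf"]) >= -1e-9).all()
            assert (np.diff(d["plc_stem"]) >= -1e-9).all()
            assert (np.diff(d["theta_rel"]) <= 1e-9).all()
            assert (np.diff(d["leaf_area"]) <= 1e-9).all()
            for col in ("psi_root", "psi_trunk", "psi_branch", "psi_leaf"):
                assert (d[col] <= 1e-12).all()

    def test_predawn_psi_non_increasing(self, panel_trajectories):
        for traj in panel_trajectories.values():
            daily = dd.daily_extremes(traj)
            assert (np.diff(daily["predawn_psi"]) <= 1e-6).all()

    def test_step_size_convergence(self, all_traits, summer_climate):
        """Halving dt_max changes the final-day leaf potential by < 0.5%."""
        t = all_traits["Que_ilex"].perturbed(leaf_area=2.0)
        soil = dd.SoilParams(pot_volume=20.0)
        runs = {}
        for dt in (600.0, 300.0):
            traj = dd.run_dehydration(t, dd.build_fractal_tree(t), soil,
                                      summer_climate,
                                      dd.SimOptions(dt_max=dt, max_days=150))
            runs[dt] = traj
        n = min(len(runs[600.0].data), len(runs[300.0].data))
        a = runs[600.0].data["psi_leaf"].iloc[n - 25:n].mean()
        b = runs[300.0].data["psi_leaf"].iloc[n - 25:n].mean()
        assert abs(a - b) / abs(b) < 5e-3

    def test_climate_shorter_than_horizon_rejected(self, all_traits):
        t = all_traits["Pin_hale"]
        clim = constant_climate(2)
        with pytest.raises(dd.SimulationError, match="covers"):
            dd.run_dehydration(t, dd.build_fractal_tree(t), dd.SoilParams(),
                               clim, dd.SimOptions(max_days=10))


class TestTraitEffectDirections:
    """Directional single-trait effects on the dehydration times."""

    @pytest.fixture(scope="class")
    def base(self, all_traits, summer_climate):
        t = all_traits["Pin_hale"].perturbed(leaf_area=2.0)
        soil = dd.SoilParams(pot_volume=20.0)
        opts = dd.SimOptions(max_days=150)

        def run(traits):
            traj = dd.run_dehydration(traits, dd.build_fractal_tree(traits),
                                      soil, summer_climate, opts)
            return dd.dehydration_times(traj, traits)

        return t, run

    def test_higher_residual_conductance_shortens_t_cav(self, base):
        t, run = base
        assert run(t.perturbed(g_res=1.5 * t.g_res)).t_cav < run(t).t_cav

    def test_more_resistant_xylem_lengthens_t_cav(self, base):
        t, run = base
        assert run(t.perturbed(p50=1.3 * t.p50)).t_cav > run(t).t_cav

    def test_higher_gs_max_shortens_t_close(self, base):
        t, run = base
        assert run(t.perturbed(gs_max=1.5 * t.gs_max)).t_close < run(t).t_close


class TestSheddingResponse:
    def test_shedding_slows_post_closure_decline(self, all_traits,
                                                 summer_climate):
        """The deciduous canopy-loss response lowers residual water loss and
        extends the time from closure to failure."""
        t = all_traits["Pop_nigr"].perturbed(leaf_area=2.0)
        t_no = t.perturbed(deciduous=False, shedding_params=None)
        soil = dd.SoilParams(pot_volume=20.0)
        opts = dd.SimOptions(max_days=150)
        traj_shed = dd.run_dehydration(t, dd.build_fractal_tree(t), soil,
                                       summer_climate, opts)
        traj_no = dd.run_dehydration(t_no, dd.build_fractal_tree(t_no), soil,
                                     summer_climate, opts)
        assert traj_shed.failed and traj_no.failed
        # both fail, but the shedding run holds out longer after closure
        assert traj_shed.duration_days > traj_no.duration_days
        # and its post-closure decline in leaf potential is slower
        day = int(traj_no.duration_days) - 1
        psi_at = {lab: tr.data.set_index("time")["psi_leaf"].loc[day * 24.0]
                  for lab, tr in (("shed", traj_shed), ("no", traj_no))}
        assert psi_at["shed"] > psi_at["no"]

    def test_canopy_loss_only_for_deciduous(self, panel_trajectories,
                                            all_traits):
        for sid, traj in panel_trajectories.items():
            la = traj.data["leaf_area"]
            if all_traits[sid].deciduous:
                assert la.iloc[-1] < 0.5 * la.iloc[0]
            else:
                assert la.iloc[-1] == la.iloc[0]


class TestPanel:
    def test_panel_of_one_equals_single_run(self, all_traits, summer_climate):
        t = all_traits["Ced_atla"]
        opts = dd.SimOptions(max_days=150)
        [p] = dd.simulate_species_panel([t], standardized=False,
                                        climate=summer_climate, options=opts)
        single = dd.run_dehydration(t, dd.build_fractal_tree(t),
                                    dd.SoilParams(), summer_climate, opts)
        pd.testing.assert_frame_equal(p.data, single.data)

    def test_standardization_overrides_allometry(self, panel_trajectories):
        first = None
        for traj in panel_trajectories.values():
            la0 = traj.data["leaf_area"].iloc[0]
            assert la0 == pytest.approx(2.0)
            assert traj.soil.pot_volume == pytest.approx(20.0)
            first = first if first is not None else la0

    def test_reproducibility(self, all_traits, summer_climate):
        t = all_traits["Pop_nigr"]
        opts = dd.SimOptions(max_days=150)
        a = dd.run_dehydration(t, dd.build_fractal_tree(t), dd.SoilParams(),
                               summer_climate, opts)
        b = dd.run_dehydration(t, dd.build_fractal_tree(t), dd.SoilParams(),
                               summer_climate, opts)
        pd.testing.assert_frame_equal(a.data, b.data)
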