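"""Trait-extraction fitters: noise-free round trips and noisy recovery."""

import math

import numpy as np
import pandas as pd
import pytest

import drydown as dd
from drydown.trait_extraction import FitError, WATER_G_PER_MOL


def mass_series_from_e(e_mmol, leaf_area, days=1, every_min=5.0, quantum=0.0,
                       m0=20000.0):
    """Constant-E balance series (g), optionally quantized."""
    t_min = np.arange(0.0, days * 1440.0, every_min)
    loss_g = e_mmol * leaf_area * 1e-3 * WATER_G_PER_MOL * t_min * 60.0
    m = m0 - loss_g
    if quantum > 0:
        m = np.round(m / quantum) * quantum
    df = pd.DataFrame({"time_min": t_min, "mass_g": m})
    df.attrs["mass_quantum"] = quantum
    return df


class TestMiddayTranspiration:
    def test_unit_conversion(self):
        """36 g lost over 2 h on 1 m2 is 0.2775 mmol m-2 s-1."""
        t_min = np.array([720.0, 780.0, 840.0])
        m = np.array([20036.0, 20018.0, 20000.0])
        df = pd.DataFrame({"time_min": t_min, "mass_g": m})
        df.attrs["mass_quantum"] = 0.0
        out = dd.midday_transpiration_from_mass(df, leaf_area=1.0)
        assert out["midday_e"].iloc[0] == pytest.approx(0.27755, abs=1e-4)

    def test_constant_mass_gives_zero(self):
        df = mass_series_from_e(0.0, 1.0)
        out = dd.midday_transpiration_from_mass(df, leaf_area=1.0)
        assert out["midday_e"].iloc[0] == 0.0

    @pytest.mark.parametrize("e_true", [0.5, 1.0, 2.0])
    def test_quantization_recovery(self, e_true):
        """50 g balance quantization: slope over the window recovers E to 10%."""
        df = mass_series_from_e(e_true, leaf_area=2.0, quantum=50.0)
        out = dd.midday_transpiration_from_mass(df, leaf_area=2.0)
        assert out["midday_e"].iloc[0] == pytest.approx(e_true, rel=0.10)

    def test_watering_flagged(self):
        df = mass_series_from_e(1.0, 1.0)
        sel = (df["time_min"] >= 720) & (df["time_min"] <= 840)
        df.loc[sel & (df["time_min"] > 780), "mass_g"] += 500.0
        out = dd.midday_transpiration_from_mass(df, leaf_area=1.0)
        assert bool(out["flagged"].iloc[0])

    def test_rejects_bad_leaf_area(self):
        with pytest.raises(ValueError):
            dd.midday_transpiration_from_mass(mass_series_from_e(1.0, 1.0), 0.0)


def weibull_points(e_max=2.0, b=2.5, c=4.0, n=30, noise=0.0, seed=None):
    rng = np.random.default_rng(seed)
    psi = -np.linspace(0.05, 2.0 * b, n)
    e = e_max * np.exp(-((-psi / b) ** c))
    if noise:
        e = e * (1.0 + rng.normal(0.0, noise, n))
    return pd.DataFrame({"midday_psi": psi, "midday_e": e})


class TestPgs88:
    def test_noise_free_round_trip(self):
        fit = dd.fit_pgs88(weibull_points())
        assert fit.e_max == pytest.approx(2.0, rel=1e-6)
        assert fit.b == pytest.approx(2.5, rel=1e-6)
        assert fit.c == pytest.approx(4.0, rel=1e-6)
        expected = -2.5 * (-math.log(0.12)) ** (1.0 / 4.0)
        assert fit.p_gs88 == pytest.approx(expected, rel=1e-6)
        assert fit.p_gs88 < 0

    def test_noisy_recovery_distribution(self):
        """5% noise, n=30: P_gs88 estimates stay within 0.15 MPa (RMSE) of
        truth over 100 seeded replicates."""
        truth = -2.5 * (-math.log(0.12)) ** 0.25
        errs = []
        for seed in range(100):
            fit = dd.fit_pgs88(weibull_points(noise=0.05, seed=seed))
            errs.append(fit.p_gs88 - truth)
        assert np.sqrt(np.mean(np.square(errs))) < 0.15

    def test_degenerate_flat_data(self):
        df = weibull_points().assign(midday_e=1.0)
        with pytest.raises(FitError, match="degenerate"):
            dd.fit_pgs88(df)

    def test_too_few_points(self):
        with pytest.raises(FitError, match=">= 6"):
            dd.fit_pgs88(weibull_points(n=4))


def pv_points(pi0=-1.52, epsilon=15.9, n=12, r_lo=0.6):
    r = np.linspace(1.0, r_lo, n)
    psi = np.array([dd.symplast_water_potential(x, pi0, epsilon).psi_total
                    for x in r])
    # full hydration gives psi = 0 which 1/psi analysis cannot use
    keep = psi < -1e-9
    return pd.DataFrame({"rwc": r[keep], "psi": psi[keep]})


class TestPressureVolume:
    def test_round_trip_against_forward_model(self):
        fit = dd.fit_pressure_volume(pv_points())
        assert fit.pi0 == pytest.approx(-1.52, rel=0.02)
        assert fit.epsilon == pytest.approx(15.9, rel=0.02)

    def test_tlp_closed_form(self):
        fit = dd.fit_pressure_volume(pv_points())
        expected = -1.52 / (1.0 + (-1.52) / 15.9)
        assert fit.tlp == pytest.approx(expected, rel=0.02)

    def test_order_invariance(self):
        pts = pv_points()
        shuffled = pts.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = dd.fit_pressure_volume(pts)
        b = dd.fit_pressure_volume(shuffled)
        assert a == b

    def test_too_few_points(self):
        with pytest.raises(FitError):
            dd.fit_pressure_volume(pv_points(n=6))


def drybox_series(g_res=1.19, area=0.1, t_air=30.0, rh=40.0, hours=24.0,
                  stomatal_pool=30.0, tau_h=1.5):
    """Two-phase branch dehydration: fast stomatal pool + constant residual."""
    vpd = dd.vapour_pressure_deficit(t_air, rh)
    slope_g_s = g_res * (vpd / 101.3) * area * 1e-3 * WATER_G_PER_MOL
    t_min = np.arange(0.0, hours * 60.0, 5.0)
    t_s = t_min * 60.0
    fast = stomatal_pool * (1.0 - np.exp(-t_s / (tau_h * 3600.0)))
    m = 500.0 - fast - slope_g_s * t_s
    return pd.DataFrame({"time_min": t_min, "mass_g": m})


class TestResidualConductance:
    def test_two_phase_recovery(self):
        df = drybox_series(g_res=1.19)
        got = dd.fit_residual_conductance(df, t_air=30.0, rh=40.0, area_m2=0.1)
        assert got == pytest.approx(1.19, rel=0.05)

    def test_zero_vpd_rejected(self):
        df = drybox_series()
        with pytest.raises(FitError, match="VPD"):
            dd.fit_residual_conductance(df, t_air=30.0, rh=100.0, area_m2=0.1)

    def test_area_normalization_contract(self):
        df = drybox_series()
        a = dd.fit_residual_conductance(df, t_air=30.0, rh=40.0, area_m2=0.1)
        b = dd.fit_residual_conductance(df, t_air=30.0, rh=40.0, area_m2=0.2)
        assert a == pytest.approx(2.0 * b, rel=1e-9)


def temperature_points(traits, levels=(30.0, 35.0, 40.0, 45.0, 50.0, 55.0),
                       noise=0.0, seed=None):
    rng = np.random.default_rng(seed)
    g = np.array([dd.residual_conductance_at_T(t, traits) for t in levels])
    if noise:
        g = g * np.exp(rng.normal(0.0, noise, len(g)))
    return pd.DataFrame({"t_air": np.array(levels), "g_res": g})


class TestTemperatureResponse:
    def test_noise_free_round_trip(self, all_traits):
        t = all_traits["Ced_atla"]  # t_p 41.3, q10_a 1.22, q10_b 1.83
        fit = dd.fit_temperature_response(temperature_points(t))
        assert fit.t_p == pytest.approx(t.t_p, abs=0.5)
        assert fit.q10_a == pytest.approx(t.q10_a, rel=0.05)
        assert fit.q10_b == pytest.approx(t.q10_b, rel=0.05)
        assert not fit.degenerate

    def test_single_slope_degenerate(self, all_traits):
        t = all_traits["Ced_atla"].perturbed(q10_b=1.22, t_p=70.0)
        fit = dd.fit_temperature_response(temperature_points(t))
        assert fit.degenerate
        assert math.isnan(fit.t_p)
        assert fit.q10_a == pytest.approx(fit.q10_b, rel=5e-3)

    def test_noisy_breakpoint_bias(self, all_traits):
        """5% multiplicative noise, 100 replicates: median t_p bias < 1 degC."""
        t = all_traits["Ced_atla"]
        tps = []
        for seed in range(100):
            fit = dd.fit_temperature_response(
                temperature_points(t, noise=0.05, seed=seed))
            if not fit.degenerate:
                tps.append(fit.t_p)
        assert len(tps) > 60
        assert abs(np.median(tps) - t.t_p) < 1.0

    def test_too_few_levels(self, all_traits):
        pts = temperature_points(all_traits["Ced_atla"],
                                 levels=(30.0, 40.0, 50.0))
        with pytest.raises(FitError):
            dd.fit_temperature_response(pts)
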