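"""Hourly climate forcing: CSV ingest and synthetic diurnal generation.

A :class:`ClimateSeries` holds hourly records of air temperature (degC),
relative humidity (%), photosynthetically active radiation
(umol m^-2 s^-1) and wind speed (m s^-1), with vapour pressure deficit (kPa)
derived per record.  Climate generation never depends on plant state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .physiology import vapour_pressure_deficit

__all__ = ["ClimateSeries", "read_climate_csv", "write_climate_csv",
           "synthesize_climate"]

_COLUMNS = ["time", "t_air", "rh", "par", "wind"]


@dataclass
class ClimateSeries:
    """Hourly atmospheric forcing with derived VPD.

    ``data`` has columns time (h, strictly increasing), t_air, rh, par, wind
    and vpd.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"climate missing columns: {missing}")
        t = df["time"].to_numpy(float)
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("climate time must be strictly increasing (>= 2 records)")
        bad_rh = df.index[(df["rh"] < 0) | (df["rh"] > 100)]
        if len(bad_rh):
            raise ValueError(f"rh out of [0, 100] at rows {list(bad_rh[:5])}")
        if (df["par"] < 0).any():
            raise ValueError("par must be >= 0")
        if "vpd" not in df.columns:
            df = df.copy()
            df["vpd"] = [vapour_pressure_deficit(t, h)
                         for t, h in zip(df["t_air"], df["rh"])]
            self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def duration_days(self) -> float:
        t = self.data["time"].to_numpy(float)
        return (t[-1] - t[0]) / 24.0

    def arrays(self) -> tuple[np.ndarray, ...]:
        """(time_h, t_air, rh, par, wind, vpd) as float arrays for the solver."""
        d = self.data
        return tuple(d[c].to_numpy(float)
                     for c in ("time", "t_air", "rh", "par", "wind", "vpd"))


def read_climate_csv(path: str | Path) -> ClimateSeries:
    """Read an hourly climate CSV; interpolate gaps of <= 3 h, reject longer.

    Expected columns: time (h), t_air (degC), rh (%), par, wind.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"climate CSV {path} missing columns: {missing}")
    t = df["time"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("climate time must be strictly increasing")
    gaps = np.diff(t)
    if np.any(gaps > 3.0):
        i = int(np.argmax(gaps > 3.0))
        raise ValueError(
            f"gap of {gaps[i]:.1f} h after time {t[i]:.1f} exceeds the 3 h "
            "interpolation limit")
    full_t = np.arange(t[0], t[-1] + 0.5, 1.0)
    out = pd.DataFrame({"time": full_t})
    for c in ("t_air", "rh", "par", "wind"):
        out[c] = np.interp(full_t, t, df[c].to_numpy(float))
    return ClimateSeries(out)


def write_climate_csv(series: ClimateSeries, path: str | Path) -> None:
    """Write the series in the same CSV dialect the reader accepts."""
    series.data[_COLUMNS + ["vpd"]].to_csv(path, index=False)


def synthesize_climate(days: int, t_min: float = 15.0, t_max: float = 32.0,
                       rh_min: float = 30.0, rh_max: float = 80.0,
                       par_max: float = 1800.0, wind: float = 1.0,
                       seed: int | None = None,
                       noise_sd: float = 0.0) -> ClimateSeries:
    """Repeating diurnal cycle typical of a constant summer's day.

    Temperature is sinusoidal with its minimum at 05:00 and maximum at 15:00;
    relative humidity runs in antiphase between its bounds; PAR is a half-sine
    between 06:00 and 20:00; wind is constant.  Every day is identical unless
    optional Gaussian noise (``noise_sd`` > 0, in degC / % / fractional PAR
    units) is switched on, in which case ``seed`` controls it.
    """
    if days < 1:
        raise ValueError(f"days must be >= 1, got {days}")
    if t_min > t_max:
        raise ValueError(f"t_min {t_min} exceeds t_max {t_max}")
    if not (0 <= rh_min <= rh_max <= 100):
        raise ValueError(f"invalid rh bounds ({rh_min}, {rh_max})")

    hours = np.arange(days * 24, dtype=float)
    h = hours % 24.0
    # piecewise sinusoid: exactly -1 at 05:00 and +1 at 15:00 (10 h rise,
    # 14 h fall; a single cosine cannot place both extremes)
    rising = (h >= 5.0) & (h <= 15.0)
    phase = np.where(rising,
                     -np.cos(np.pi * (h - 5.0) / 10.0),
                     np.cos(np.pi * ((h - 15.0) % 24.0) / 14.0))
    t_air = (t_min + t_max) / 2.0 + (t_max - t_min) / 2.0 * phase
    rh = (rh_min + rh_max) / 2.0 - (rh_max - rh_min) / 2.0 * phase
    par = np.where((h >= 6.0) & (h <= 20.0),
                   par_max * np.sin(np.pi * (h - 6.0) / 14.0), 0.0)
    wind_arr = np.full_like(hours, float(wind))

    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        t_air = t_air + rng.normal(0.0, noise_sd, t_air.shape)
        rh = np.clip(rh + rng.normal(0.0, noise_sd, rh.shape), 0.0, 100.0)
        par = np.clip(par * (1.0 + rng.normal(0.0, noise_sd / 100.0, par.shape)),
                      0.0, None)

    return ClimateSeries(pd.DataFrame({
        "time": hours, "t_air": t_air, "rh": rh, "par": par, "wind": wind_arr}))
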