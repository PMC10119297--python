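"""Seeded synthetic wind and ambient-gas generators.

These generators stand in for the field conditions that drive the closed
control loop: a wind series (speed + direction, 4-second cadence by default)
and an ambient CO2/O3 series (1-minute cadence). They aim for the first and
second moments and the diurnal shape of midwestern growing-season
conditions, not for meteorological realism.

Wind speed is the absolute value of a discrete Ornstein-Uhlenbeck (mean
reverting) recursion; with the default parameters (mean 2 m/s, stationary
s.d. ~0.8 m/s) the reflected mass is negligible, so the sample mean tracks
``mean_speed``. Direction is a latent OU process attracted to the prevailing
direction (SSW, 202.5 deg, by default) wrapped onto (0, 360]. Samples slower
than ``calm_threshold`` are emitted with direction 0, the convention under
which 0 deg means calm and 360 deg means true north.

Both generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter


@dataclass(frozen=True)
class WindParams:
    """Wind-process parameters.

    mean_speed : long-run mean speed, m/s
    reversion_rate : OU pull toward the mean, 1/s
    volatility : OU noise intensity, m/s per sqrt(s); stationary s.d. is
        volatility / sqrt(2 * reversion_rate)
    prevailing_direction : attractor of the direction process, degrees
    direction_concentration : dimensionless tightness; the stationary
        directional s.d. scales as 1/sqrt(concentration) (~42 deg at 1.0)
    calm_threshold : speeds below this are emitted as calm (direction 0), m/s
    """

    mean_speed: float = 2.0
    reversion_rate: float = 0.02
    volatility: float = 0.16
    prevailing_direction: float = 202.5
    direction_concentration: float = 1.0
    calm_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.mean_speed < 0 or self.volatility < 0:
            raise ValueError("mean_speed and volatility must be non-negative")
        if self.reversion_rate <= 0:
            raise ValueError("reversion_rate must be positive")
        if self.direction_concentration <= 0:
            raise ValueError("direction_concentration must be positive")


@dataclass(frozen=True)
class AmbientParams:
    """Diurnal-cycle parameters of the ambient series.

    CO2 follows a cosine with its nocturnal (pre-dawn) maximum; O3 a
    Gaussian bump peaking in the afternoon. Values are clipped to the
    plausibility windows (250-1500 ppm CO2, 0-500 ppb O3). noise_sd applies
    to both series in their native units.
    """

    co2_mean: float = 400.0  # ppm
    co2_diurnal_amp: float = 30.0  # ppm
    o3_midday_peak: float = 60.0  # ppb
    o3_night_floor: float = 20.0  # ppb
    noise_sd: float = 2.0
    co2_peak_hour: float = 5.0
    o3_peak_hour: float = 14.0
    o3_peak_width_h: float = 3.5

    def __post_init__(self) -> None:
        for name in ("co2_mean", "co2_diurnal_amp", "o3_midday_peak",
                     "o3_night_floor", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.o3_midday_peak < self.o3_night_floor:
            raise ValueError("o3_midday_peak must be >= o3_night_floor")


def _ou_path(rng: np.ndarray, mean: float, theta: float, sigma: float,
             dt: float, n: int, x0: float) -> np.ndarray:
    """Discrete OU recursion x[k+1] = a*x[k] + (1-a)*mean + sigma*sqrt(dt)*eps,
    a = 1 - theta*dt, started at x0; evaluated with a linear filter."""
    a = 1.0 - theta * dt
    if not -1.0 < a < 1.0:
        raise ValueError("reversion_rate * dt must lie in (0, 2) for stability")
    drive = (1.0 - a) * mean + sigma * np.sqrt(dt) * rng
    drive[0] += a * x0
    return lfilter([1.0], [1.0, -a], drive)


def gen_wind(
    params: WindParams,
    seed: int,
    start: "pd.Timestamp | str",
    duration: float,
    dt: float = 4.0,
) -> pd.DataFrame:
    """Generate a wind series covering ``duration`` seconds from ``start``.

    Returns a DataFrame with columns ``timestamp``, ``speed`` (m/s) and
    ``direction`` (degrees, 0 = calm, 360 = north) at cadence ``dt``.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("need dt > 0 and duration >= dt")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    eps_speed = rng.standard_normal(n)
    eps_dir = rng.standard_normal(n)

    speed = np.abs(
        _ou_path(eps_speed, params.mean_speed, params.reversion_rate,
                 params.volatility, dt, n, params.mean_speed)
    )

    theta_d = 0.01 * params.direction_concentration
    sigma_d = 6.0  # deg per sqrt(s); stationary s.d. = 6/sqrt(2*theta_d)
    latent_dir = _ou_path(eps_dir, params.prevailing_direction, theta_d,
                          sigma_d, dt, n, params.prevailing_direction)
    direction = np.mod(latent_dir, 360.0)
    direction[direction == 0.0] = 360.0  # non-calm north is encoded as 360
    calm = speed < params.calm_threshold
    direction[calm] = 0.0

    timestamps = pd.Timestamp(start) + pd.to_timedelta(np.arange(n) * dt, unit="s")
    return pd.DataFrame(
        {"timestamp": timestamps, "speed": speed, "direction": direction}
    )


def gen_ambient(
    params: AmbientParams,
    seed: int,
    start: "pd.Timestamp | str",
    duration: float,
    dt: float = 60.0,
) -> pd.DataFrame:
    """Generate a 1-minute ambient CO2/O3 series covering ``duration`` seconds.

    Returns a DataFrame with columns ``timestamp``, ``co2`` (ppm) and
    ``o3`` (ppb), clipped to the plausibility windows.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("need dt > 0 and duration >= dt")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    timestamps = pd.Timestamp(start) + pd.to_timedelta(np.arange(n) * dt, unit="s")
    hour = (
        (timestamps - timestamps.normalize()).total_seconds().to_numpy() / 3600.0
    )

    co2 = params.co2_mean + params.co2_diurnal_amp * np.cos(
        2.0 * np.pi * (hour - params.co2_peak_hour) / 24.0
    )
    o3 = params.o3_night_floor + (params.o3_midday_peak - params.o3_night_floor) * np.exp(
        -0.5 * ((hour - params.o3_peak_hour) / params.o3_peak_width_h) ** 2
    )
    if params.noise_sd > 0:
        co2 = co2 + params.noise_sd * rng.standard_normal(n)
        o3 = o3 + params.noise_sd * rng.standard_normal(n)
    co2 = np.clip(co2, 250.0, 1500.0)
    o3 = np.clip(o3, 0.0, 500.0)
    return pd.DataFrame({"timestamp": timestamps, "co2": co2, "o3": o3})
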