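"""Seasonal exposure indices, fumigation efficiency, and wind-rose tables.

Ozone exposure indices accumulate hourly daylight (8:00-19:00) means over a
season, expressed in ppm.h:

* **AOT40** - sum of the hourly excess over 40 ppb, for hours above 40 ppb.
* **SUM06** - sum of the full hourly concentration, for hours above 60 ppb
  (strict inequality, as defined; an inclusive variant is available since
  part of the literature uses >= 0.06 ppm).
* **W126** - sigmoidally weighted sum: each hourly concentration C (ppm)
  contributes C / (1 + 4403 * exp(-126 * C)), favouring high concentrations
  without a hard threshold.

Fumigation efficiency is the percentage of fumigation-on minutes whose
measured concentration lies within 10% (or 20%) of the setpoint, pooled over
a treatment's plots; off minutes are excluded from the denominator.

Wind roses bin non-calm samples into 12 x 30-degree direction sectors
(centred on 0, 30, ... 330 deg) and four speed classes; samples with
direction 0 are calm and reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .species import GasSpecies, UnitError

PPB_PER_PPM = 1000.0


@dataclass(frozen=True)
class IndexThresholds:
    """Constants of the exposure indices and the daylight window."""

    aot40_threshold: float = 40.0  # ppb
    sum06_threshold: float = 60.0  # ppb
    w126_a: float = 4403.0  # dimensionless
    w126_b: float = 126.0  # per ppm
    daylight_start_hour: int = 8
    daylight_end_hour: int = 19  # inclusive: hours labelled 08:00..19:00
    sum06_inclusive: bool = False


DEFAULT_THRESHOLDS = IndexThresholds()


@dataclass(frozen=True)
class ExposureSummary:
    """Seasonal accumulations of the three indices, ppm.h."""

    season: str
    aot40: float
    sum06: float
    w126: float
    n_hours_used: int


@dataclass(frozen=True)
class EfficiencyReport:
    """Share of fumigation-on minutes near the setpoint.

    ``pct_within_10``/``pct_within_20`` are None when there were no
    on-minutes (the statistic is undefined, not zero).
    """

    year: int | None
    species: GasSpecies
    plot: int | None  # None = pooled over plots
    minutes_on: int
    pct_within_10: float | None
    pct_within_20: float | None


#: Speed classes of the wind rose, m/s: [0,2), [2,4), [4,6), >=6.
SPEED_CLASS_EDGES = (0.0, 2.0, 4.0, 6.0, math.inf)
SPEED_CLASS_LABELS = ("0-2", "2-4", "4-6", ">6")


@dataclass(frozen=True)
class WindRoseTable:
    """Binned wind-rose frequencies (percent of all samples).

    ``frequencies`` is a 12 x 4 frame: rows are sector centres (deg), columns
    the speed classes. Cell percentages plus ``calm_pct`` sum to 100.
    ``mean_speed`` is the mean over non-calm samples.
    """

    frequencies: pd.DataFrame
    calm_pct: float
    mean_speed: float
    n_samples: int


def _daylight_hourly(
    hourly: pd.DataFrame, thresholds: IndexThresholds
) -> pd.Series:
    if "species" in hourly.columns and len(hourly):
        kinds = {GasSpecies.parse(s) for s in hourly["species"].unique()}
        if kinds != {GasSpecies.O3}:
            raise UnitError("exposure indices are defined for O3 hourly data")
    hod = pd.to_datetime(hourly["hour"]).dt.hour
    window = (hod >= thresholds.daylight_start_hour) & (
        hod <= thresholds.daylight_end_hour
    )
    return hourly.loc[window, "mean"].dropna()


def aot40(hourly_o3: pd.DataFrame, thresholds: IndexThresholds = DEFAULT_THRESHOLDS) -> float:
    """Accumulated exposure over the 40 ppb threshold, ppm.h.

    ``hourly_o3`` needs columns ``hour`` and ``mean`` (ppb); missing hours
    are skipped.
    """
    o3 = _daylight_hourly(hourly_o3, thresholds).to_numpy()
    excess = o3[o3 > thresholds.aot40_threshold] - thresholds.aot40_threshold
    return float(excess.sum() / PPB_PER_PPM)


def sum06(hourly_o3: pd.DataFrame, thresholds: IndexThresholds = DEFAULT_THRESHOLDS) -> float:
    """Sum of full hourly concentrations above 60 ppb, ppm.h."""
    o3 = _daylight_hourly(hourly_o3, thresholds).to_numpy()
    if thresholds.sum06_inclusive:
        kept = o3[o3 >= thresholds.sum06_threshold]
    else:
        kept = o3[o3 > thresholds.sum06_threshold]
    return float(kept.sum() / PPB_PER_PPM)


def w126_weight(c_ppm: np.ndarray | float,
                thresholds: IndexThresholds = DEFAULT_THRESHOLDS) -> np.ndarray | float:
    """Sigmoidal weight 1 / (1 + 4403 * exp(-126 * C_ppm)); in (0, 1) and
    strictly increasing in concentration."""
    return 1.0 / (1.0 + thresholds.w126_a * np.exp(-thresholds.w126_b * np.asarray(c_ppm, dtype=float)))


def w126(hourly_o3: pd.DataFrame, thresholds: IndexThresholds = DEFAULT_THRESHOLDS) -> float:
    """Sigmoidally weighted seasonal daylight sum, ppm.h. Concentrations are
    converted to ppm inside the weight."""
    o3_ppm = _daylight_hourly(hourly_o3, thresholds).to_numpy() / PPB_PER_PPM
    return float(np.sum(o3_ppm * w126_weight(o3_ppm, thresholds)))


def exposure_summary(
    hourly_o3: pd.DataFrame,
    season: str,
    thresholds: IndexThresholds = DEFAULT_THRESHOLDS,
) -> ExposureSummary:
    """All three indices for one season of hourly O3 means."""
    used = _daylight_hourly(hourly_o3, thresholds)
    return ExposureSummary(
        season=season,
        aot40=aot40(hourly_o3, thresholds),
        sum06=sum06(hourly_o3, thresholds),
        w126=w126(hourly_o3, thresholds),
        n_hours_used=int(len(used)),
    )


def target_percentages(
    minutes: pd.DataFrame,
    tolerances: tuple[float, float] = (0.10, 0.20),
    year: int | None = None,
    plot: int | None = None,
) -> EfficiencyReport:
    """Percentage of fumigation-on minutes within each tolerance of setpoint.

    A minute counts as within tolerance when |C - setpoint| <= tol * setpoint
    (boundaries inclusive). Off minutes are excluded entirely. Pass a frame
    restricted to one plot (and set ``plot``) for a per-plot breakdown; the
    default pools all rows, the reporting convention of the seasonal record.
    """
    lo, hi = sorted(tolerances)
    species = GasSpecies.parse(minutes["species"].iloc[0]) if len(minutes) else GasSpecies.CO2
    on = minutes.loc[minutes["system_on"].astype(bool)]
    n_on = int(len(on))
    if n_on == 0:
        return EfficiencyReport(year, species, plot, 0, None, None)
    if on["setpoint"].isna().any():
        raise ValueError("every fumigation-on minute must carry a setpoint")
    err = (on["concentration"] - on["setpoint"]).abs()
    bound_lo = lo * on["setpoint"]
    bound_hi = hi * on["setpoint"]
    pct_lo = 100.0 * float((err <= bound_lo).sum()) / n_on
    pct_hi = 100.0 * float((err <= bound_hi).sum()) / n_on
    return EfficiencyReport(year, species, plot, n_on, pct_lo, pct_hi)


def wind_rose(wind: pd.DataFrame) -> WindRoseTable:
    """Bin a wind series into the 12-sector x 4-class frequency table.

    ``wind`` needs columns ``speed`` (m/s) and ``direction`` (deg; 0 = calm,
    360 = north). Sector k is centred on 30k deg and spans +/- 15 deg.
    """
    n = len(wind)
    centres = [i * 30 for i in range(12)]
    freq = pd.DataFrame(0.0, index=centres, columns=list(SPEED_CLASS_LABELS))
    freq.index.name = "sector_deg"
    if n == 0:
        return WindRoseTable(freq, calm_pct=0.0, mean_speed=0.0, n_samples=0)
    direction = wind["direction"].to_numpy(dtype=float)
    speed = wind["speed"].to_numpy(dtype=float)
    calm = direction == 0.0
    n_calm = int(calm.sum())
    d = direction[~calm] % 360.0  # 360 (north) falls in the sector centred on 0
    s = speed[~calm]
    sector = np.rint(d / 30.0).astype(int) % 12
    sclass = np.digitize(s, SPEED_CLASS_EDGES[1:-1], right=False)
    for sec in range(12):
        in_sec = sector == sec
        for ci in range(4):
            freq.iloc[sec, ci] = 100.0 * np.sum(in_sec & (sclass == ci)) / n
    mean_speed = float(s.mean()) if len(s) else 0.0
    return WindRoseTable(
        frequencies=freq,
        calm_pct=100.0 * n_calm / n,
        mean_speed=mean_speed,
        n_samples=n,
    )


def load_efficiency_archive() -> pd.DataFrame:
    """Published seasonal efficiency record (2001-2021): columns ``year``,
    ``pct10_co2``, ``pct20_co2``, ``pct10_o3``, ``pct20_o3``."""
    path = resources.files("facesim") / "data" / "efficiency_archive.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, comment="#")
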