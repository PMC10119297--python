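"""Quality control for 1-minute fumigation records.

Three stages, mirroring how archived FACE fumigation data are screened:

1. **Repeat flagging** — an analyzer or logger that sticks produces the same
   concentration minute after minute. Maximal runs of identical values (at
   written file precision) of at least ``min_run`` minutes are flagged.
   Flags are advisory: a separate exclusion step (an explicit list, or the
   optional automatic heuristic) converts flags into invalidity, standing in
   for the human review the archive applied.
2. **Filter window** — concentrations outside the plausibility window
   (250-1500 ppm CO2, 0-500 ppb O3, boundaries inclusive) are invalid.
3. **Hourly aggregation** — mean and median over the valid minutes of each
   clock hour; hours with fewer than ``min_valid`` valid minutes are
   reported missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .species import GasSpecies, UnitError


@dataclass(frozen=True)
class FilterWindow:
    """Inclusive plausibility window for 1-minute concentrations."""

    species: GasSpecies
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("need low < high")


DEFAULT_FILTER_WINDOWS: dict[GasSpecies, FilterWindow] = {
    GasSpecies.CO2: FilterWindow(GasSpecies.CO2, 250.0, 1500.0),
    GasSpecies.O3: FilterWindow(GasSpecies.O3, 0.0, 500.0),
}


@dataclass(frozen=True)
class RepeatFlag:
    """A maximal run of identical consecutive 1-minute values."""

    plot_id: int
    species: GasSpecies
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    run_length: int
    repeated_value: float


class OrderingError(ValueError):
    """Input minutes are not in increasing time order."""


class CadenceError(ValueError):
    """Input is not at the 1-minute cadence this stage expects."""


def _check_minute_cadence(timestamps: pd.Series) -> None:
    if len(timestamps) < 2:
        return
    deltas = timestamps.diff().dropna().dt.total_seconds()
    if (deltas <= 0).any():
        raise OrderingError("minute records must be strictly time-ordered")
    # Reject coarser (already aggregated) input outright; gaps are fine.
    if deltas.min() > 60.0:
        raise CadenceError(
            "input cadence is coarser than 1 minute - looks already aggregated"
        )


def flag_repeats(
    minutes: pd.DataFrame, min_run: int = 5, decimals: int = 1
) -> list[RepeatFlag]:
    """Flag maximal runs of >= ``min_run`` consecutive identical values.

    Values are compared at written file precision (``decimals`` places,
    canonical string formatting) so float noise cannot split a stuck run.
    ``minutes`` must hold one plot+species, strictly time-ordered.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    if minutes.empty:
        return []
    _check_minute_cadence(minutes["timestamp"])
    plot_id = int(minutes["plot_id"].iloc[0])
    species = GasSpecies.parse(minutes["species"].iloc[0])
    shown = [
        f"{v:.{decimals}f}" if pd.notna(v) else None
        for v in minutes["concentration"]
    ]
    ts = minutes["timestamp"].reset_index(drop=True)
    flags: list[RepeatFlag] = []
    i, n = 0, len(shown)
    while i < n:
        j = i
        while j + 1 < n and shown[j + 1] == shown[i] and shown[i] is not None:
            j += 1
        run = j - i + 1
        if shown[i] is not None and run >= min_run:
            flags.append(
                RepeatFlag(
                    plot_id=plot_id,
                    species=species,
                    start_time=ts[i],
                    end_time=ts[j],
                    run_length=run,
                    repeated_value=float(shown[i]),
                )
            )
        i = j + 1
    return flags


def apply_filter(
    minutes: pd.DataFrame,
    window: FilterWindow,
    exclusions: pd.DataFrame | None = None,
) -> pd.Series:
    """Boolean validity mask: within the filter window and not excluded.

    ``exclusions`` is an optional frame of (plot_id, species, start_time,
    end_time) intervals (inclusive) built from reviewed repeat flags.
    Missing concentrations are invalid.
    """
    species = minutes["species"].map(GasSpecies.parse) if len(minutes) else pd.Series([], dtype=object)
    if len(minutes) and (species != window.species).any():
        raise UnitError(
            f"filter window is for {window.species.value} but records contain "
            f"other species"
        )
    conc = minutes["concentration"]
    mask = conc.ge(window.low) & conc.le(window.high)
    if exclusions is not None and len(exclusions):
        for _, row in exclusions.iterrows():
            if GasSpecies.parse(row["species"]) is not window.species:
                continue
            hit = (
                (minutes["plot_id"] == row["plot_id"])
                & (minutes["timestamp"] >= pd.Timestamp(row["start_time"]))
                & (minutes["timestamp"] <= pd.Timestamp(row["end_time"]))
            )
            mask &= ~hit
    return mask.rename("valid")


def auto_exclusions(
    minutes: pd.DataFrame,
    flags: list[RepeatFlag],
    ambient_minutes: pd.DataFrame,
    min_run: int = 15,
    rel_tol: float = 0.10,
) -> pd.DataFrame:
    """Heuristic replacement for manual flag review: exclude runs of at
    least ``min_run`` minutes whose stuck value differs from the concurrent
    ambient mean by more than ``rel_tol`` (a stuck sensor far from ambient is
    implausible as real air). Returns an exclusion frame for
    :func:`apply_filter`.
    """
    rows = []
    amb_col = {GasSpecies.CO2: "co2", GasSpecies.O3: "o3"}
    amb = ambient_minutes.set_index("timestamp")
    for flag in flags:
        if flag.run_length < min_run:
            continue
        window = amb.loc[flag.start_time:flag.end_time, amb_col[flag.species]]
        if window.empty:
            continue
        ref = float(window.mean())
        if ref > 0 and abs(flag.repeated_value - ref) / ref > rel_tol:
            rows.append(
                {
                    "plot_id": flag.plot_id,
                    "species": flag.species.value,
                    "start_time": flag.start_time,
                    "end_time": flag.end_time,
                }
            )
    return pd.DataFrame(rows, columns=["plot_id", "species", "start_time", "end_time"])


def aggregate_hourly(
    minutes: pd.DataFrame,
    mask: pd.Series,
    min_valid: int = 30,
) -> pd.DataFrame:
    """Aggregate valid 1-minute values to clock-hour mean and median.

    Hours are clock-aligned [HH:00, HH+1:00). ``n_valid`` counts the valid
    contributing minutes; ``mean`` and ``median`` are NaN when
    ``n_valid < min_valid``. Input must hold one plot+species at 1-minute
    cadence (coarser input is rejected, not silently re-averaged).
    """
    if not 1 <= min_valid <= 60:
        raise ValueError("min_valid must be in 1..60")
    if minutes.empty:
        return pd.DataFrame(columns=["hour", "plot_id", "species", "mean", "median", "n_valid"])
    _check_minute_cadence(minutes["timestamp"])
    df = minutes.loc[:, ["timestamp", "plot_id", "species", "concentration"]].copy()
    df["valid"] = mask.to_numpy()
    df["hour"] = df["timestamp"].dt.floor("h")
    valid_conc = df["concentration"].where(df["valid"])
    grouped = df.assign(vc=valid_conc).groupby(["hour", "plot_id", "species"], sort=True)
    out = grouped["vc"].agg(
        mean="mean", median="median", n_valid=lambda s: int(s.notna().sum())
    ).reset_index()
    thin = out["n_valid"] < min_valid
    out.loc[thin, ["mean", "median"]] = np.nan
    return out[["hour", "plot_id", "species", "mean", "median", "n_valid"]]
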