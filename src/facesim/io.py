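"""Readers and writers for the minute and hourly CSV dialects.

The archived fumigation record stores one file of 1-minute records per day,
named ``Avg_MMDDYY``, and one hourly file per year, named
``YYYY_HrlyFumData_ByRing``. The column sheets of the archive itself are not
bundled here, so this package defines its own documented dialect with the
same naming conventions plus a header-mapping layer for ingesting foreign
files: pass ``mapping={foreign_header: internal_name}`` to the readers.

All writers are deterministic - fixed column order, fixed numeric formatting
(concentrations and setpoints to 1 decimal, wind speed and valve to 2,
direction to 1), stable row ordering - so outputs are byte-stable and
diffable across runs.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import re
from pathlib import Path

import pandas as pd

from .simulate import MINUTE_COLUMNS

log = logging.getLogger("facesim")

HOURLY_COLUMNS = ["hour", "plot_id", "species", "mean", "median", "n_valid"]

_MINUTE_NAME_RE = re.compile(r"^Avg_(\d{2})(\d{2})(\d{2})(\.csv)?$")


class DialectError(ValueError):
    """Filename or file content violates the documented dialect."""


def minute_filename(day: _dt.date) -> str:
    """``Avg_MMDDYY.csv`` for one day of 1-minute records."""
    return f"Avg_{day:%m%d%y}.csv"


def parse_minute_filename(name: str) -> _dt.date:
    """Recover the date from an ``Avg_MMDDYY`` filename.

    Century pivot: YY 00-79 -> 2000s, 80-99 -> 1900s (unambiguous for the
    2001-2021 record).
    """
    m = _MINUTE_NAME_RE.match(Path(name).name)
    if not m:
        raise DialectError(f"filename {name!r} does not match 'Avg_MMDDYY'")
    mm, dd, yy = int(m.group(1)), int(m.group(2)), int(m.group(3))
    year = 2000 + yy if yy < 80 else 1900 + yy
    try:
        return _dt.date(year, mm, dd)
    except ValueError as exc:
        raise DialectError(f"filename {name!r} encodes no valid date") from exc


def hourly_filename(year: int) -> str:
    return f"{year}_HrlyFumData_ByRing.csv"


def _format_minutes(df: pd.DataFrame) -> pd.DataFrame:
    out = df.loc[:, MINUTE_COLUMNS].sort_values(
        ["timestamp", "plot_id", "species"], kind="mergesort"
    )
    return pd.DataFrame(
        {
            "timestamp": out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S"),
            "plot_id": out["plot_id"].astype(int),
            "species": out["species"],
            "concentration": out["concentration"].map(
                lambda v: "" if pd.isna(v) else f"{v:.1f}"
            ),
            "setpoint": out["setpoint"].map(lambda v: "" if pd.isna(v) else f"{v:.1f}"),
            "valve_setting": out["valve_setting"].map(lambda v: f"{v:.2f}"),
            "wind_speed": out["wind_speed"].map(lambda v: f"{v:.2f}"),
            "wind_direction": out["wind_direction"].map(lambda v: f"{v:.1f}"),
            "system_on": out["system_on"].astype(bool).astype(int),
        }
    )


def write_minute_file(minutes: pd.DataFrame, path: str | Path) -> Path:
    """Write one day of minute records to an ``Avg_MMDDYY`` file.

    The rows must all fall on the date encoded in the filename.
    """
    path = Path(path)
    day = parse_minute_filename(path.name)
    dates = pd.to_datetime(minutes["timestamp"]).dt.date.unique()
    if len(minutes) and (len(dates) != 1 or dates[0] != day):
        raise DialectError(
            f"rows dated {sorted(map(str, dates))} do not match filename date {day}"
        )
    _format_minutes(minutes).to_csv(path, index=False, lineterminator="\n")
    return path


def write_minute_files(minutes: pd.DataFrame, directory: str | Path) -> list[Path]:
    """Split a minute-record frame by calendar day and write one
    ``Avg_MMDDYY`` file per day into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for day, chunk in minutes.groupby(minutes["timestamp"].dt.date, sort=True):
        written.append(write_minute_file(chunk, directory / minute_filename(day)))
    return written


def read_minute_file(
    path: str | Path, mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read one ``Avg_MMDDYY`` file into a typed minute-record frame.

    ``mapping`` renames foreign headers to the internal schema before
    validation, which is how archived files with their own column sheets are
    ingested. Rows whose concentration is missing are retained with NaN and
    logged. Row dates must match the filename date.
    """
    path = Path(path)
    day = parse_minute_filename(path.name)
    df = pd.read_csv(path)
    if mapping:
        df = df.rename(columns=mapping)
    missing = [c for c in MINUTE_COLUMNS if c not in df.columns]
    if missing:
        raise DialectError(f"{path.name}: missing columns {missing}")
    df = df.loc[:, MINUTE_COLUMNS].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    bad = df["timestamp"].dt.date != day
    if bad.any():
        raise DialectError(
            f"{path.name}: {int(bad.sum())} rows dated outside the filename date "
            f"(first at line {int(bad.idxmax()) + 2})"
        )
    df["plot_id"] = df["plot_id"].astype(int)
    for col in ("concentration", "setpoint", "valve_setting", "wind_speed", "wind_direction"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["system_on"] = df["system_on"].astype(int).astype(bool)
    n_nan = int(df["concentration"].isna().sum())
    if n_nan:
        log.warning("%s: %d rows with missing concentration retained", path.name, n_nan)
    return df.sort_values(["timestamp", "plot_id", "species"], kind="mergesort").reset_index(drop=True)


def read_minute_dir(
    directory: str | Path, mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read and concatenate every ``Avg_*`` file in a directory."""
    files = sorted(Path(directory).glob("Avg_*"))
    if not files:
        raise DialectError(f"no Avg_MMDDYY files found in {directory}")
    return pd.concat(
        [read_minute_file(f, mapping) for f in files], ignore_index=True
    )


def write_hourly_file(hourly: pd.DataFrame, path: str | Path) -> Path:
    """Write hourly records (one calendar year) to a
    ``YYYY_HrlyFumData_ByRing`` file. Deterministic ordering and formatting."""
    path = Path(path)
    if not len(hourly):
        path.write_text(",".join(HOURLY_COLUMNS) + "\n")
        return path
    years = pd.to_datetime(hourly["hour"]).dt.year.unique()
    if len(years) != 1:
        raise DialectError(f"hourly records span years {sorted(years)}; one file per year")
    out = hourly.loc[:, HOURLY_COLUMNS].sort_values(
        ["hour", "plot_id", "species"], kind="mergesort"
    )
    formatted = pd.DataFrame(
        {
            "hour": pd.to_datetime(out["hour"]).dt.strftime("%Y-%m-%dT%H:%M:%S"),
            "plot_id": out["plot_id"].astype(int),
            "species": out["species"],
            "mean": out["mean"].map(lambda v: "" if pd.isna(v) else f"{v:.2f}"),
            "median": out["median"].map(lambda v: "" if pd.isna(v) else f"{v:.2f}"),
            "n_valid": out["n_valid"].astype(int),
        }
    )
    formatted.to_csv(path, index=False, lineterminator="\n")
    return path


def read_hourly_file(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in HOURLY_COLUMNS if c not in df.columns]
    if missing:
        raise DialectError(f"{Path(path).name}: missing columns {missing}")
    df["hour"] = pd.to_datetime(df["hour"])
    df["n_valid"] = df["n_valid"].astype(int)
    if ((df["n_valid"] < 0) | (df["n_valid"] > 60)).any():
        raise DialectError("n_valid outside 0..60")
    return df


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> Path:
    """Serialize a run manifest deterministically (sorted keys, no wall-clock
    content) so identical runs produce identical bytes."""
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
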