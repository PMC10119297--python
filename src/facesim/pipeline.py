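"""End-to-end pipeline: simulate (or ingest) -> QC -> hourly -> metrics.

Mirrors the processing chain applied to the archived record: pick the
year's experiments from the registry, screen the 1-minute files, aggregate
to hourly means/medians, then compute seasonal efficiency, exposure indices
and wind-rose tables. Every run writes a machine-readable manifest (seeds,
parameters, file checksums, record counts) so two runs with the same config
are byte-identical and diffable.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .environment import AmbientParams, WindParams
from .io import (
    read_minute_dir,
    sha256_file,
    write_hourly_file,
    write_manifest,
    write_minute_files,
    hourly_filename,
)
from .metrics import exposure_summary, target_percentages, wind_rose
from .qc import (
    DEFAULT_FILTER_WINDOWS,
    aggregate_hourly,
    apply_filter,
    auto_exclusions,
    flag_repeats,
)
from .registry import ExperimentConfig, load_registry
from .simulate import (
    FumigationSchedule,
    concat_minutes,
    generate_environment,
    simulate_experiment,
)
from .species import GasSpecies


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _select_experiments(
    experiments: list[ExperimentConfig],
    year: int,
    treatment: str | None,
    crop: str | None,
) -> list[ExperimentConfig]:
    chosen = [e for e in experiments if e.year == year]
    if treatment is not None:
        want = frozenset(GasSpecies.parse(t) for t in treatment.split("+"))
        chosen = [e for e in chosen if e.treatment == want]
    if crop is not None:
        chosen = [e for e in chosen if e.crop == crop]
    if not chosen:
        raise PipelineError(f"stage select: no experiment matches year={year}")
    return chosen


def _truncated(config: ExperimentConfig, days: int | None) -> ExperimentConfig:
    if days is None:
        return config
    end = config.treating_date + _dt.timedelta(days=days)
    return dataclasses.replace(config, harvest_date=end)


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured pipeline and return the manifest.

    ``config`` is a dict or a YAML file with keys::

        source: simulate | directory
        registry: null (packaged) | path
        year: season to process
        treatment: optional selector, e.g. "CO2" or "CO2+O3"
        crop: optional selector
        seed: integer (simulate source)
        days: optional truncation of the season, in days
        input_dir: directory of Avg_MMDDYY files (directory source)
        out_dir: output directory
        qc: {min_run: 5, min_valid: 30, auto_exclude: false}
        schedule: {start_hour: 8, end_hour: 19}

    Stages run in order simulate/ingest -> qc -> hourly -> metrics; any
    failure aborts with the stage name. Outputs: per-day minute files (when
    simulating), a QC report, one hourly file, efficiency/exposure/wind-rose
    tables and ``manifest.json``.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config)
    source = cfg.get("source", "simulate")
    out_dir = Path(cfg["out_dir"])
    qc_cfg = {"min_run": 5, "min_valid": 30, "auto_exclude": False, **cfg.get("qc", {})}
    sched_cfg = {"start_hour": 8, "end_hour": 19, **cfg.get("schedule", {})}

    # -- pre-flight ---------------------------------------------------------
    if source == "directory":
        input_dir = Path(cfg.get("input_dir", ""))
        if not input_dir.is_dir():
            raise PipelineError(f"stage preflight: input_dir {input_dir} is not a directory")
    elif source != "simulate":
        raise PipelineError(f"stage preflight: unknown source {source!r}")
    registry_path = cfg.get("registry")
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "facesim_version": __version__,
        "config": {k: cfg[k] for k in sorted(cfg) if k != "out_dir"},
        "stages": {},
        "files": {},
    }

    # -- simulate / ingest --------------------------------------------------
    ambient = None
    try:
        if source == "simulate":
            experiments = load_registry(registry_path)
            chosen = _select_experiments(
                experiments, int(cfg["year"]), cfg.get("treatment"), cfg.get("crop")
            )
            schedule = FumigationSchedule(**sched_cfg)
            seed = int(cfg.get("seed", 0))
            frames = []
            for i, exp in enumerate(chosen):
                exp = _truncated(exp, cfg.get("days"))
                env = generate_environment(exp, seed + i)
                frames.append(concat_minutes(simulate_experiment(exp, env, schedule=schedule)))
                ambient = env.ambient  # shared-site series; last one suffices
            minutes = pd.concat(frames, ignore_index=True)
            minute_dir = out_dir / "minute"
            written = write_minute_files(minutes, minute_dir)
            manifest["stages"]["simulate"] = {
                "experiments": len(chosen),
                "minute_files": len(written),
                "rows": int(len(minutes)),
            }
        else:
            minutes = read_minute_dir(cfg["input_dir"], cfg.get("mapping"))
            manifest["stages"]["ingest"] = {"rows": int(len(minutes))}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage simulate/ingest: {exc}") from exc

    # -- qc -----------------------------------------------------------------
    try:
        flags_rows = []
        masks = {}
        for (plot, species_name), grp in minutes.groupby(["plot_id", "species"], sort=True):
            species = GasSpecies.parse(species_name)
            grp = grp.sort_values("timestamp").reset_index(drop=True)
            flags = flag_repeats(grp, min_run=qc_cfg["min_run"])
            exclusions = None
            if qc_cfg["auto_exclude"] and ambient is not None and flags:
                exclusions = auto_exclusions(grp, flags, ambient)
            mask = apply_filter(grp, DEFAULT_FILTER_WINDOWS[species], exclusions)
            masks[(plot, species)] = (grp, mask)
            for f in flags:
                flags_rows.append(
                    {
                        "plot_id": f.plot_id,
                        "species": f.species.value,
                        "start_time": f.start_time.isoformat(),
                        "end_time": f.end_time.isoformat(),
                        "run_length": f.run_length,
                        "repeated_value": f.repeated_value,
                    }
                )
        qc_report = out_dir / "qc_report.csv"
        pd.DataFrame(
            flags_rows,
            columns=["plot_id", "species", "start_time", "end_time", "run_length", "repeated_value"],
        ).to_csv(qc_report, index=False, lineterminator="\n")
        n_invalid = sum(int((~m).sum()) for _, m in masks.values())
        manifest["stages"]["qc"] = {
            "flags": len(flags_rows),
            "invalid_minutes": n_invalid,
        }
    except Exception as exc:
        raise PipelineError(f"stage qc: {exc}") from exc

    # -- hourly -------------------------------------------------------------
    try:
        hourly = pd.concat(
            [aggregate_hourly(grp, mask, min_valid=qc_cfg["min_valid"]) for grp, mask in masks.values()],
            ignore_index=True,
        ).sort_values(["hour", "plot_id", "species"], kind="mergesort")
        year = int(pd.to_datetime(hourly["hour"]).dt.year.iloc[0])
        hourly_path = out_dir / hourly_filename(year)
        write_hourly_file(hourly, hourly_path)
        manifest["stages"]["hourly"] = {"rows": int(len(hourly))}
    except Exception as exc:
        raise PipelineError(f"stage hourly: {exc}") from exc

    # -- metrics ------------------------------------------------------------
    try:
        eff_rows = []
        for species_name, grp in minutes.groupby("species", sort=True):
            rep = target_percentages(grp, year=year)
            eff_rows.append(_eff_row(rep, pooled=True))
            for plot, pgrp in grp.groupby("plot_id", sort=True):
                rep = target_percentages(pgrp, year=year, plot=int(plot))
                eff_rows.append(_eff_row(rep, pooled=False))
        pd.DataFrame(
            eff_rows,
            columns=["year", "species", "plot", "minutes_on", "pct_within_10", "pct_within_20"],
        ).to_csv(out_dir / "efficiency.csv", index=False, lineterminator="\n", float_format="%.4f")

        o3_hourly = hourly.loc[hourly["species"] == GasSpecies.O3.value]
        if len(o3_hourly):
            summ = exposure_summary(o3_hourly, season=str(year))
            pd.DataFrame([dataclasses.asdict(summ)]).to_csv(
                out_dir / "exposure.csv", index=False, lineterminator="\n", float_format="%.6f"
            )

        rose_rows = []
        for plot, pgrp in minutes.drop_duplicates(["plot_id", "timestamp"]).groupby("plot_id", sort=True):
            rose = wind_rose(pgrp.rename(columns={"wind_speed": "speed", "wind_direction": "direction"}))
            flat = rose.frequencies.stack()
            for (sec, cls), pct in flat.items():
                rose_rows.append({"plot_id": int(plot), "sector_deg": sec, "speed_class": cls, "pct": pct})
            rose_rows.append({"plot_id": int(plot), "sector_deg": "calm", "speed_class": "", "pct": rose.calm_pct})
        pd.DataFrame(rose_rows, columns=["plot_id", "sector_deg", "speed_class", "pct"]).to_csv(
            out_dir / "windrose.csv", index=False, lineterminator="\n", float_format="%.4f"
        )
        manifest["stages"]["metrics"] = {"efficiency_rows": len(eff_rows)}
    except Exception as exc:
        raise PipelineError(f"stage metrics: {exc}") from exc

    for f in sorted(out_dir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out_dir))] = sha256_file(f)
    write_manifest(manifest, out_dir / "manifest.json")
    return manifest


def _eff_row(rep, pooled: bool) -> dict:
    return {
        "year": rep.year,
        "species": rep.species.value,
        "plot": "" if pooled else rep.plot,
        "minutes_on": rep.minutes_on,
        "pct_within_10": rep.pct_within_10,
        "pct_within_20": rep.pct_within_20,
    }
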