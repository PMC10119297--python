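"""Experiment registry: which plots ran which gas treatment in which season.

The packaged registry (``data/registry.yaml``) mirrors the facility's
experiment record for 2001-2021: one entry per experiment with year,
treatment gases, crop, plot ids, planting/treating/harvest dates and the gas
setpoints. Setpoints are either a constant concentration in the species'
native unit (e.g. 550 ppm CO2) or a dimensionless multiple of the concurrent
ambient concentration (e.g. 1.5 x ambient O3); from 2009 onward some ozone
experiments assign a different constant to every plot.

The registry file format is a documented YAML schema (see the packaged file
header); :func:`load_registry` validates every entry and reports schema
violations with the offending entry index and field.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

from .species import GasSpecies

_VALID_PLOTS = range(1, 33)


class RegistryError(ValueError):
    """Schema or consistency violation in a registry file."""


class UnresolvedSetpointError(ValueError):
    """An ambient-multiple setpoint was resolved without a valid ambient."""


@dataclass(frozen=True)
class SetpointSpec:
    """A gas setpoint: a constant concentration or a multiple of ambient.

    ``value`` is a concentration in the species' native unit when
    ``kind == "constant"`` and a dimensionless factor when
    ``kind == "ambient_multiple"``.
    """

    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "ambient_multiple"):
            raise RegistryError(f"unknown setpoint kind: {self.kind!r}")
        if not self.value > 0:
            raise RegistryError("setpoint value must be positive")


def resolve_setpoint(spec: SetpointSpec, ambient_now: float | None = None) -> float:
    """Resolve a setpoint to a concentration in the ambient's unit.

    Constant setpoints pass through unchanged; ambient-multiple setpoints
    require a positive concurrent ambient concentration.
    """
    if spec.kind == "constant":
        return spec.value
    if ambient_now is None or not ambient_now > 0:
        raise UnresolvedSetpointError(
            "ambient_multiple setpoint needs a positive ambient concentration"
        )
    return spec.value * ambient_now


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment season: treatment gases, crop, plots, dates, setpoints."""

    year: int
    treatment: frozenset[GasSpecies]
    crop: str
    plot_setpoints: dict[int, dict[GasSpecies, SetpointSpec]]
    planting_date: _dt.date
    treating_date: _dt.date
    harvest_date: _dt.date | None
    annotation: str = ""
    alternate_setpoints: dict[int, dict[GasSpecies, SetpointSpec]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not self.plot_setpoints:
            raise RegistryError("experiment has no plots")
        for plot, per_species in self.plot_setpoints.items():
            if plot not in _VALID_PLOTS:
                raise RegistryError(f"plot id {plot} outside 1..32")
            missing = self.treatment - set(per_species)
            if missing:
                raise RegistryError(
                    f"plot {plot} lacks a setpoint for {sorted(s.value for s in missing)}"
                )
        if self.treating_date < self.planting_date:
            raise RegistryError("treating_date precedes planting_date")
        if self.harvest_date is not None and self.harvest_date <= self.treating_date:
            raise RegistryError("harvest_date not after treating_date")

    @property
    def plots(self) -> list[int]:
        return sorted(self.plot_setpoints)

    @property
    def treatment_label(self) -> str:
        return "+".join(sorted(s.value for s in self.treatment))

    @property
    def season_end(self) -> _dt.date:
        """Harvest date, or the conventional growing-period end (Oct 15)
        when no harvest was recorded."""
        if self.harvest_date is not None:
            return self.harvest_date
        return _dt.date(self.year, 10, 15)


def _parse_date(raw: object, entry: int, fld: str) -> _dt.date:
    if isinstance(raw, _dt.date):
        return raw
    try:
        return _dt.date.fromisoformat(str(raw))
    except ValueError as exc:
        raise RegistryError(f"entry {entry}: bad date in field {fld!r}: {raw!r}") from exc


def _parse_setpoint(raw: object, entry: int) -> SetpointSpec:
    if not isinstance(raw, dict) or "kind" not in raw or "value" not in raw:
        raise RegistryError(f"entry {entry}: setpoint needs 'kind' and 'value'")
    try:
        return SetpointSpec(kind=str(raw["kind"]), value=float(raw["value"]))
    except (TypeError, ValueError) as exc:
        raise RegistryError(f"entry {entry}: bad setpoint {raw!r}: {exc}") from exc


def _parse_species_setpoints(
    raw: dict, plots: list[int], entry: int
) -> dict[int, dict[GasSpecies, SetpointSpec]]:
    """Expand the file's per-species setpoint block into per-plot maps.

    Each species block is either a single setpoint shared by all plots or a
    ``by_plot`` mapping of plot id to setpoint.
    """
    out: dict[int, dict[GasSpecies, SetpointSpec]] = {p: {} for p in plots}
    for species_name, block in raw.items():
        species = GasSpecies.parse(species_name)
        if isinstance(block, dict) and "by_plot" in block:
            by_plot = block["by_plot"]
            if set(map(int, by_plot)) != set(plots):
                raise RegistryError(
                    f"entry {entry}: by_plot keys do not match the plot list"
                )
            for plot, sp in by_plot.items():
                out[int(plot)][species] = _parse_setpoint(sp, entry)
        else:
            spec = _parse_setpoint(block, entry)
            for plot in plots:
                out[plot][species] = spec
    return out


def _parse_entry(raw: dict, entry: int) -> ExperimentConfig:
    for fld in ("year", "treatment", "crop", "plots", "planting", "treating", "setpoints"):
        if fld not in raw:
            raise RegistryError(f"entry {entry}: missing field {fld!r}")
    treatment = frozenset(GasSpecies.parse(s) for s in raw["treatment"])
    plots = [int(p) for p in raw["plots"]]
    if len(set(plots)) != len(plots):
        raise RegistryError(f"entry {entry}: duplicate plot ids")
    setpoints = _parse_species_setpoints(raw["setpoints"], plots, entry)
    alternates: dict[int, dict[GasSpecies, SetpointSpec]] = {}
    if "alternate_setpoints" in raw:
        alternates = _parse_species_setpoints(raw["alternate_setpoints"], plots, entry)
    harvest = raw.get("harvest")
    return ExperimentConfig(
        year=int(raw["year"]),
        treatment=treatment,
        crop=str(raw["crop"]),
        plot_setpoints=setpoints,
        planting_date=_parse_date(raw["planting"], entry, "planting"),
        treating_date=_parse_date(raw["treating"], entry, "treating"),
        harvest_date=None if harvest is None else _parse_date(harvest, entry, "harvest"),
        annotation=str(raw.get("annotation", "")),
        alternate_setpoints=alternates,
    )


def _check_overlaps(experiments: Iterable[ExperimentConfig]) -> None:
    seen: dict[tuple[int, GasSpecies, int], int] = {}
    for cfg in experiments:
        for plot in cfg.plots:
            for species in cfg.treatment:
                key = (cfg.year, species, plot)
                if key in seen:
                    raise RegistryError(
                        f"plot {plot} assigned twice to {species.value} in {cfg.year}"
                    )
                seen[key] = 1


def load_registry(path: str | Path | None = None) -> list[ExperimentConfig]:
    """Load a registry file (the packaged default when ``path`` is None).

    Returns all experiments sorted by year, then treatment label, then first
    plot id. Raises :class:`RegistryError` on schema violations or on a plot
    assigned twice to the same gas within one year.
    """
    if path is None:
        text = (resources.files("facesim") / "data" / "registry.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc is None:
        return []
    if not isinstance(doc, dict) or "experiments" not in doc:
        raise RegistryError("registry file must contain an 'experiments' list")
    raw_entries = doc["experiments"] or []
    experiments = [_parse_entry(raw, i) for i, raw in enumerate(raw_entries)]
    _check_overlaps(experiments)
    experiments.sort(key=lambda c: (c.year, c.treatment_label, c.plots[0]))
    return experiments


def dump_registry(experiments: Iterable[ExperimentConfig], path: str | Path) -> None:
    """Serialize experiments back to the registry YAML schema (round-trips
    with :func:`load_registry`)."""

    def _sp_block(per_plot: dict[int, dict[GasSpecies, SetpointSpec]]):
        species_all = sorted({s for m in per_plot.values() for s in m}, key=lambda s: s.value)
        block = {}
        for species in species_all:
            specs = {p: per_plot[p][species] for p in per_plot if species in per_plot[p]}
            unique = {(s.kind, s.value) for s in specs.values()}
            if len(unique) == 1:
                one = next(iter(specs.values()))
                block[species.value] = {"kind": one.kind, "value": one.value}
            else:
                block[species.value] = {
                    "by_plot": {
                        p: {"kind": s.kind, "value": s.value} for p, s in sorted(specs.items())
                    }
                }
        return block

    entries = []
    for cfg in experiments:
        entry = {
            "year": cfg.year,
            "treatment": sorted(s.value for s in cfg.treatment),
            "crop": cfg.crop,
            "plots": cfg.plots,
            "planting": cfg.planting_date.isoformat(),
            "treating": cfg.treating_date.isoformat(),
            "harvest": None if cfg.harvest_date is None else cfg.harvest_date.isoformat(),
            "setpoints": _sp_block(cfg.plot_setpoints),
        }
        if cfg.annotation:
            entry["annotation"] = cfg.annotation
        if cfg.alternate_setpoints:
            entry["alternate_setpoints"] = _sp_block(cfg.alternate_setpoints)
        entries.append(entry)
    Path(path).write_text(yaml.safe_dump({"version": 1, "experiments": entries}, sort_keys=False))
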