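"""Gas species and their native concentration units.

Every concentration in the package is carried in the species' native unit:
parts per million (ppm) for CO2 and parts per billion (ppb) for O3. Keeping
the unit fixed per species avoids silent unit mixing between the controller
(whose coefficient magnitudes are unit-specific) and the exposure metrics
(which convert ppb to ppm only at the point of the index formulas).
"""

from __future__ import annotations

import enum


class GasSpecies(str, enum.Enum):
    """A fumigation gas. The native unit is fixed by the species."""

    CO2 = "CO2"
    O3 = "O3"

    @property
    def native_unit(self) -> str:
        return "ppm" if self is GasSpecies.CO2 else "ppb"

    @classmethod
    def parse(cls, value: "GasSpecies | str") -> "GasSpecies":
        if isinstance(value, cls):
            return value
        key = str(value).strip().upper().replace("OZONE", "O3")
        try:
            return cls(key)
        except ValueError as exc:
            raise ValueError(f"unknown gas species: {value!r}") from exc


class UnitError(ValueError):
    """Raised when concentrations from different species/units are mixed."""
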