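"""Concentration units and the analyte-concentration record.

All internal risk arithmetic is done in µg/L; mg/L and ng/L are handled by
exact power-of-ten conversion at the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = ["Analyte", "Condition", "AnalyteConcentration", "convert", "UnitError"]


class UnitError(ValueError):
    """Raised when a concentration is missing a unit or units cannot be reconciled."""


#: µg/L per one unit of each supported concentration unit.
_UG_PER_L = {
    "mg_per_L": 1e3,
    "ug_per_L": 1.0,
    "ng_per_L": 1e-3,
}


def convert(value: float, unit: str, to: str) -> float:
    """Convert ``value`` between mass-concentration units (exact powers of ten)."""
    try:
        return value * _UG_PER_L[unit] / _UG_PER_L[to]
    except KeyError as exc:
        raise UnitError(f"unknown concentration unit {exc.args[0]!r}") from exc


class Analyte(str, Enum):
    """Quantified analyte in an exposure medium: total metal or free ion."""

    Ti = "Ti"
    Zn = "Zn"
    Ag = "Ag"
    Zn_ion = "Zn_ion"
    Ag_ion = "Ag_ion"


class Condition(str, Enum):
    """Illumination condition during the release procedure."""

    light = "light"
    dark = "dark"
    na = "na"


@dataclass(frozen=True)
class AnalyteConcentration:
    """A measured analyte concentration in a product's release medium."""

    product: str
    analyte: Analyte
    condition: Condition
    value: float
    unit: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "analyte", Analyte(self.analyte))
        object.__setattr__(self, "condition", Condition(self.condition))
        if self.unit not in _UG_PER_L:
            raise UnitError(f"unknown concentration unit {self.unit!r}")
        if not self.value > 0:
            raise ValueError("concentration must be positive")

    def in_unit(self, to: str) -> float:
        return convert(self.value, self.unit, to)
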