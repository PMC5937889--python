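"""Physical constants and the fixed unit table used throughout the package.

All internal computation is SI; convenience units (mV, pA, pF, um, ...) exist
only at the API boundary.  Only the units the model needs are supported — this
is deliberately not a general unit-algebra system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CONSTANTS",
    "PhysicalConstants",
    "Quantity",
    "UnknownUnitError",
    "to_si",
    "convert",
    "thermal_voltage",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA values for the constants entering the model equations.

    ``gas_constant == boltzmann * avogadro`` and
    ``faraday == elementary_charge * avogadro`` hold by construction.
    """

    elementary_charge: float = 1.602176634e-19  # C
    avogadro: float = 6.02214076e23  # 1/mol
    boltzmann: float = 1.380649e-23  # J/K

    @property
    def gas_constant(self) -> float:
        """R in J/(mol K)."""
        return self.boltzmann * self.avogadro

    @property
    def gas_constant_kcal(self) -> float:
        """R in kcal/(mol K); 1 kcal = 4184 J (thermochemical calorie)."""
        return self.gas_constant / 4184.0

    @property
    def faraday(self) -> float:
        """F in C/mol."""
        return self.elementary_charge * self.avogadro


CONSTANTS = PhysicalConstants()

# unit -> (SI scale factor, SI unit name)
_UNIT_TABLE: dict[str, tuple[float, str]] = {
    "mV": (1e-3, "V"),
    "V": (1.0, "V"),
    "pA": (1e-12, "A"),
    "A": (1.0, "A"),
    "pF": (1e-12, "F"),
    "F": (1.0, "F"),
    "um": (1e-6, "m"),
    "m": (1.0, "m"),
    "um^3": (1e-18, "m^3"),
    "m^3": (1.0, "m^3"),
    "L": (1e-3, "m^3"),
    "K": (1.0, "K"),
    "s": (1.0, "s"),
    "pmol": (1e-12, "mol"),
    "mol": (1.0, "mol"),
    "kcal/mol": (4184.0, "J/mol"),
    "J/mol": (1.0, "J/mol"),
    "J": (1.0, "J"),
    "pW": (1e-12, "W"),
    "W": (1.0, "W"),
    "W/(m*K)": (1.0, "W/(m*K)"),
    "J/(K*m^3)": (1.0, "J/(K*m^3)"),
    "pA/pF": (1.0, "A/F"),
    "A/F": (1.0, "A/F"),
    "K/s": (1.0, "K/s"),
    "K/m": (1.0, "K/m"),
}

# aliases accepted on input (Unicode spellings)
_ALIASES = {
    "µm": "um",
    "μm": "um",
    "µm³": "um^3",
    "μm³": "um^3",
    "um3": "um^3",
    "W/(m·K)": "W/(m*K)",
    "J/(K·m³)": "J/(K*m^3)",
}


class UnknownUnitError(ValueError):
    """Raised for a unit outside the supported table."""

    def __init__(self, unit: str):
        super().__init__(
            f"unknown unit {unit!r}; supported units: {sorted(_UNIT_TABLE)}"
        )
        self.unit = unit


@dataclass(frozen=True)
class Quantity:
    """A magnitude with one of the supported units."""

    magnitude: float
    unit: str

    def to_si(self) -> "Quantity":
        return to_si(self)


def _canonical(unit: str) -> str:
    unit = _ALIASES.get(unit, unit)
    if unit not in _UNIT_TABLE:
        raise UnknownUnitError(unit)
    return unit


def to_si(q: Quantity) -> Quantity:
    """Convert a quantity to its SI base/derived unit.

    >>> to_si(Quantity(100, "pA"))
    Quantity(magnitude=1e-10, unit='A')
    """
    unit = _canonical(q.unit)
    scale, si_unit = _UNIT_TABLE[unit]
    return Quantity(q.magnitude * scale, si_unit)


def convert(magnitude: float, from_unit: str, to_unit: str) -> float:
    """Convert between two units sharing the same SI base."""
    fu, tu = _canonical(from_unit), _canonical(to_unit)
    fs, fsi = _UNIT_TABLE[fu]
    ts, tsi = _UNIT_TABLE[tu]
    if fsi != tsi:
        raise ValueError(f"incompatible units {from_unit!r} -> {to_unit!r}")
    return magnitude * fs / ts


def thermal_voltage(temperature_K: float, *, legacy_2_3: bool = False) -> float:
    """Nernst slope 2.303*R*T/F in volts (~61.5 mV per pH unit at 310 K).

    The chemiosmotic pmf relation carries a factor conventionally rounded to
    2.3; by default the exact ln(10) is used.  ``legacy_2_3=True`` reproduces
    the literal 2.3.
    """
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K} K")
    factor = 2.3 if legacy_2_3 else math.log(10.0)
    return factor * CONSTANTS.gas_constant * temperature_K / CONSTANTS.faraday
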