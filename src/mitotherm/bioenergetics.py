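"""Electrochemical energy source: pmf, UCP1 proton current, power, proton flux.

Sign conventions
----------------
The inner-membrane potential is physically negative inside; here ``delta_psi``
is stored as a nonnegative *magnitude*.  ``delta_pH = pH_in - pH_out`` is
positive when the matrix is alkaline, and a positive ``delta_pH`` *adds* to the
pmf — this matches the chemiosmotic relation pmf = Δψ − (2.3RT/F)·ΔpH written
with the outward gradient ΔpH = pH_out − pH_in.  The inward thermogenic proton
current is a positive number; all outputs are magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .units import CONSTANTS, thermal_voltage

__all__ = [
    "PmfComponents",
    "MitoplastElectrical",
    "ThermogenicDrive",
    "compute_pmf",
    "ucp1_current",
    "thermogenic_power",
    "proton_flux",
]

# empirical mitoplast patch-clamp ranges (warn, don't reject, outside them)
CAPACITANCE_RANGE_PF = (0.5, 1.2)
CURRENT_DENSITY_RANGE = (60.0, 110.0)  # pA/pF


@dataclass(frozen=True)
class PmfComponents:
    """Electrical and chemical components of the proton-motive force.

    delta_psi_mV : magnitude of the electrical gradient (mV, >= 0)
    delta_pH     : pH_in - pH_out (positive = alkaline matrix)
    temperature_K: absolute temperature
    """

    delta_psi_mV: float
    delta_pH: float = 0.0
    temperature_K: float = 310.0

    def __post_init__(self):
        if self.temperature_K <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature_K} K")
        if self.delta_psi_mV < 0:
            raise ValueError(
                "delta_psi_mV is a magnitude and must be >= 0 "
                f"(got {self.delta_psi_mV} mV); the negative-inside sign is implicit"
            )


@dataclass(frozen=True)
class MitoplastElectrical:
    """Membrane capacitance and UCP1 current density of a mitoplast."""

    capacitance_pF: float
    current_density_pA_per_pF: float

    def __post_init__(self):
        if self.capacitance_pF <= 0:
            raise ValueError(f"capacitance must be positive, got {self.capacitance_pF} pF")
        if self.current_density_pA_per_pF < 0:
            raise ValueError(
                f"current density must be >= 0, got {self.current_density_pA_per_pF} pA/pF"
            )
        lo, hi = CAPACITANCE_RANGE_PF
        if not lo <= self.capacitance_pF <= hi:
            warnings.warn(
                f"capacitance {self.capacitance_pF} pF outside the typical "
                f"mitoplast range {lo}-{hi} pF",
                stacklevel=2,
            )
        lo, hi = CURRENT_DENSITY_RANGE
        if self.current_density_pA_per_pF and not lo <= self.current_density_pA_per_pF <= hi:
            warnings.warn(
                f"current density {self.current_density_pA_per_pF} pA/pF outside the "
                f"typical UCP1 range {lo}-{hi} pA/pF",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ThermogenicDrive:
    """pmf + proton current + efficiency; power is derived (P = pmf * I)."""

    proton_current_pA: float
    pmf_mV: float
    efficiency: float = 1.0
    power_W: float = field(init=False)

    def __post_init__(self):
        if self.proton_current_pA < 0:
            raise ValueError(
                f"inward thermogenic current must be >= 0, got {self.proton_current_pA} pA"
            )
        if self.pmf_mV < 0:
            raise ValueError(f"pmf magnitude must be >= 0, got {self.pmf_mV} mV")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError(f"efficiency must be in [0, 1], got {self.efficiency}")
        object.__setattr__(
            self, "power_W", thermogenic_power(self.pmf_mV, self.proton_current_pA)
        )


def compute_pmf(components: PmfComponents, *, legacy_2_3: bool = False) -> float:
    """Proton-motive force magnitude in mV.

    pmf = |Δψ| + (2.303 R T / F) * ΔpH with ΔpH = pH_in − pH_out.  With a
    purely electrical gradient (ΔpH = 0) this returns delta_psi_mV unchanged;
    one alkaline pH unit at 310 K adds ~61.5 mV.
    """
    nernst_mV = 1e3 * thermal_voltage(components.temperature_K, legacy_2_3=legacy_2_3)
    return components.delta_psi_mV + nernst_mV * components.delta_pH


def ucp1_current(electrical: MitoplastElectrical) -> float:
    """UCP1-mediated proton current in pA: capacitance x current density.

    With the canonical 1.0 pF and 100 pA/pF this is the 100 pA working value.
    """
    return electrical.capacitance_pF * electrical.current_density_pA_per_pF


def thermogenic_power(pmf_mV: float, current_pA: float) -> float:
    """Heat power P = pmf * I_H+ in watts (200 mV x 100 pA -> 20 pW)."""
    if pmf_mV < 0:
        raise ValueError(f"pmf magnitude must be >= 0, got {pmf_mV} mV")
    if current_pA < 0:
        raise ValueError(f"current must be >= 0, got {current_pA} pA")
    return (pmf_mV * 1e-3) * (current_pA * 1e-12)


def proton_flux(current_pA: float) -> tuple[float, float]:
    """Proton turnover of a current: (protons/s, mol/s).

    100 pA corresponds to ~6.24e8 protons per second.
    """
    if current_pA < 0:
        raise ValueError(f"current must be >= 0, got {current_pA} pA")
    per_second = current_pA * 1e-12 / CONSTANTS.elementary_charge
    return per_second, per_second / CONSTANTS.avogadro
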