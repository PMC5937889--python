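"""Ratiometric fluorescence thermometry and heating-rate estimation.

The normalized intensity ratio nr of a thermosensitive over a thermoneutral
mitochondrial dye follows an Arrhenius-type law with activation energy Ea:

    1/T - 1/Tref = -(R/Ea) * ln nr

so nr = 1 at the reference temperature and, with the relation as written,
nr < 1 maps to T < Tref.  Ea is molar (kcal/mol), so the Boltzmann factor is
evaluated as the molar gas constant R; using the per-particle k_B with a molar
Ea would be off by Avogadro's number.  Because the dye literature does not fix
the sensitivity direction, ``sensitivity_sign=-1`` flips the sign of ln nr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np

from .thermal import TemperatureTrace
from .units import CONSTANTS

__all__ = [
    "CalibrationParams",
    "DyeRatioTrace",
    "CalibrationRangeError",
    "ratio_to_temperature",
    "temperature_to_ratio",
    "trace_to_temperature",
    "estimate_rate",
    "RateSummary",
]

# temperatures implying the dye is far outside its calibrated range
_CAL_RANGE_K = (250.0, 350.0)


class CalibrationRangeError(ValueError):
    """The ratio falls outside the invertible range of the calibration."""


@dataclass(frozen=True)
class CalibrationParams:
    """Arrhenius calibration of the dye pair.

    activation_energy_kcal_per_mol : measured activation energy (default 6.55)
    reference_temperature_K        : temperature at which nr = 1 (no default
                                     in the file format; must be supplied)
    sensitivity_sign               : +1 keeps the relation as written
                                     (nr < 1 => T < Tref); -1 flips it
    """

    reference_temperature_K: float
    activation_energy_kcal_per_mol: float = 6.55
    sensitivity_sign: int = 1

    def __post_init__(self):
        if self.activation_energy_kcal_per_mol <= 0:
            raise ValueError("activation energy must be positive")
        if self.reference_temperature_K <= 0:
            raise ValueError("reference temperature must be positive")
        if self.sensitivity_sign not in (1, -1):
            raise ValueError("sensitivity_sign must be +1 or -1")

    @property
    def gas_constant_over_Ea(self) -> float:
        """R/Ea in 1/K (molar gas constant over molar activation energy)."""
        return CONSTANTS.gas_constant_kcal / self.activation_energy_kcal_per_mol


@dataclass(frozen=True)
class DyeRatioTrace:
    """Time series of normalized dye intensity ratios plus its calibration."""

    times_s: np.ndarray
    nr: np.ndarray
    calibration: CalibrationParams
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.nr, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and nr must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        bad = np.flatnonzero(~(v > 0))
        if bad.size:
            raise ValueError(f"nr must be > 0; offending sample indices: {bad.tolist()}")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "nr", v)

    def __len__(self) -> int:
        return self.times_s.size


def ratio_to_temperature(nr, cal: CalibrationParams):
    """Invert the calibration: T = 1 / (1/Tref - sign*(R/Ea)*ln nr).

    nr = 1 returns Tref exactly.  Raises for non-positive ratios and for
    ratios so large that the denominator reaches zero (outside the
    calibration's invertible range); temperatures far outside the dye's
    physiological calibration range trigger a warning.
    """
    nr_arr = np.asarray(nr, dtype=float)
    if np.any(~(nr_arr > 0)):
        bad = np.flatnonzero(~(np.atleast_1d(nr_arr) > 0))
        raise ValueError(f"nr must be > 0; offending sample indices: {bad.tolist()}")
    denom = 1.0 / cal.reference_temperature_K - (
        cal.sensitivity_sign * cal.gas_constant_over_Ea * np.log(nr_arr)
    )
    if np.any(denom <= 0):
        raise CalibrationRangeError(
            "ratio outside the invertible calibration range (1/T reached zero)"
        )
    T = 1.0 / denom
    lo, hi = _CAL_RANGE_K
    if np.any((np.atleast_1d(T) < lo) | (np.atleast_1d(T) > hi)):
        warnings.warn(
            f"converted temperature outside the calibrated range [{lo}, {hi}] K",
            stacklevel=2,
        )
    return T if nr_arr.ndim else float(T)


def temperature_to_ratio(T, cal: CalibrationParams):
    """Forward calibration: nr = exp(-sign*(Ea/R)*(1/T - 1/Tref)).

    Exact inverse of :func:`ratio_to_temperature`; T = Tref gives nr = 1.
    """
    T_arr = np.asarray(T, dtype=float)
    if np.any(~(T_arr > 0)):
        raise ValueError("temperature must be positive")
    exponent = (
        -cal.sensitivity_sign
        * (1.0 / T_arr - 1.0 / cal.reference_temperature_K)
        / cal.gas_constant_over_Ea
    )
    nr = np.exp(exponent)
    return nr if T_arr.ndim else float(nr)


def trace_to_temperature(trace: DyeRatioTrace) -> TemperatureTrace:
    """Pointwise conversion of a ratio trace to a temperature trace."""
    values = ratio_to_temperature(trace.nr, trace.calibration)
    return TemperatureTrace(
        trace.times_s,
        values,
        label=trace.label or "converted from dye ratio",
        metadata={
            "Tref_K": trace.calibration.reference_temperature_K,
            "Ea_kcal_per_mol": trace.calibration.activation_energy_kcal_per_mol,
            "sensitivity_sign": trace.calibration.sensitivity_sign,
            **trace.metadata,
        },
    )


@dataclass(frozen=True)
class RateSummary:
    max_rate_K_per_s: float
    mean_rate_K_per_s: float
    window_samples: int


def _window_slopes(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    n = t.size
    slopes = np.empty(n - window + 1)
    for i in range(slopes.size):
        tt = t[i : i + window]
        yy = y[i : i + window]
        tc = tt - tt.mean()
        slopes[i] = tc @ (yy - yy.mean()) / (tc @ tc)
    return slopes


def estimate_rate(
    trace: TemperatureTrace, window: int = 5
) -> tuple[np.ndarray, RateSummary]:
    """Heating-rate estimates from a temperature trace.

    Per-window least-squares slopes (sliding window of ``window`` samples,
    noise-robust analogue of a pointwise derivative) plus a summary holding
    the maximum windowed slope and the time-averaged rate, i.e. the global
    least-squares slope over the whole trace.  On a noiseless linear trace
    every window recovers the true slope exactly.
    """
    if window < 2:
        raise ValueError("window must span at least 2 samples")
    if len(trace) < window:
        raise ValueError(
            f"trace has {len(trace)} samples, fewer than window={window}"
        )
    slopes = _window_slopes(trace.times_s, trace.values_K, window)
    tc = trace.times_s - trace.times_s.mean()
    mean_rate = tc @ (trace.values_K - trace.values_K.mean()) / (tc @ tc)
    return slopes, RateSummary(
        max_rate_K_per_s=float(np.max(slopes)),
        mean_rate_K_per_s=float(mean_rate),
        window_samples=window,
    )
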