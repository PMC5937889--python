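"""Config parsing and trace-file I/O.

Trace CSV dialect: comma-separated, UTF-8, ``.`` decimal, required header —
``time_s,temperature_K`` for temperature traces and ``time_s,nr`` for dye
ratio traces (the latter optionally preceded by ``# Tref_K=... Ea_kcal_mol=...``
comment lines carrying the calibration).  Config files are YAML or JSON with
flat, unit-suffixed keys; unknown keys are rejected so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .thermal import TemperatureTrace
from .thermometry import CalibrationParams, DyeRatioTrace

__all__ = [
    "ConfigError",
    "RunConfig",
    "parse_config",
    "read_temperature_csv",
    "write_temperature_csv",
    "read_ratio_csv",
    "write_ratio_csv",
    "read_schedule_yaml",
]


class ConfigError(ValueError):
    """A configuration file violates the schema."""


# key -> (default, description with unit); None default means optional-without-default
_SCHEMA: dict[str, tuple[Any, str]] = {
    "delta_psi_mV": (200.0, "electrical gradient magnitude [mV]"),
    "delta_pH": (0.0, "pH_in - pH_out [dimensionless]"),
    "temperature_K": (310.0, "absolute temperature [K]"),
    "capacitance_pF": (1.0, "mitoplast membrane capacitance [pF]"),
    "current_density_pA_per_pF": (100.0, "UCP1 current density [pA/pF]"),
    "eta": (1.0, "thermogenic efficiency in [0, 1]"),
    "volume_um3": (1.0, "mitochondrial volume [um^3]"),
    "kappa_W_per_mK": (0.6, "thermal conductivity [W/(m*K)]"),
    "C_J_per_Km3": (4.18e6, "volumetric heat capacity [J/(K*m^3)]"),
    "cell_diameter_um": (20.0, "cell diameter [um]"),
    "cytosol_pH": (7.4, "cytosol pH"),
    "glucose_uptake_pmol_per_h": (0.18, "glucose uptake [pmol/h per cell]"),
    "protons_per_glucose": (24, "H+ yielded per glucose [count]"),
    "n_mitochondria": (1000, "mitochondria per cell [count]"),
    "Ea_kcal_mol": (6.55, "dye activation energy [kcal/mol]"),
    "Tref_K": (None, "thermometry reference temperature [K] (required for thermometry)"),
    "sensitivity_sign": (1, "dye sensitivity direction (+1 or -1)"),
    "observed_rate_K_per_s": (0.005, "observed sustained heating rate [K/s]"),
    "observed_demand_pmol_per_s": (1e-3, "observed sustained proton demand [pmol/s]"),
    "n_points": (256, "diffusion grid points [count]"),
    "r_outer_um": (50.0, "diffusion bath radius [um]"),
    "dt_s": (1e-3, "time step [s]"),
    "t_end_s": (0.2, "integration end time [s]"),
    "seed": (0, "random seed [int]"),
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration with provenance (user-set vs default) per key."""

    values: dict[str, Any]
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def require(self, key: str) -> Any:
        if self.values.get(key) is None:
            raise ConfigError(
                f"missing required key '{key}' ({_SCHEMA[key][1]}); no default exists"
            )
        return self.values[key]


def _validate(raw: dict[str, Any]) -> RunConfig:
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(
            f"unknown config keys {sorted(unknown)}; known keys: {sorted(_SCHEMA)}"
        )
    values, provenance = {}, {}
    for key, (default, _desc) in _SCHEMA.items():
        if key in raw:
            val = raw[key]
            if val is not None and not isinstance(val, (int, float)):
                raise ConfigError(
                    f"key '{key}' must be numeric ({_SCHEMA[key][1]}), got {val!r}"
                )
            values[key] = val
            provenance[key] = "user"
        else:
            values[key] = default
            provenance[key] = "default"
    return RunConfig(values, provenance)


def parse_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config file, apply overrides, validate, fill defaults."""
    raw: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        if path.suffix == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    return _validate(raw)


def _read_csv(path: str | Path, expected_cols: list[str]) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    header_meta: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line.lstrip("#").split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    header_meta[k] = float(v)
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != expected_cols:
        raise ValueError(
            f"{path}: expected header {','.join(expected_cols)}, got {','.join(df.columns)}"
        )
    for col in expected_cols:
        if not np.issubdtype(df[col].dtype, np.number) or df[col].isna().any():
            bad = df.index[df[col].isna() | ~df[col].apply(np.isreal)].tolist()
            raise ValueError(f"{path}: non-numeric values in '{col}' at data rows {bad}")
    t = df[expected_cols[0]].to_numpy()
    if t.size >= 2:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValueError(
                f"{path}: time not strictly increasing at data row {int(bad[0]) + 3}"
            )
    return df, header_meta


def read_temperature_csv(path: str | Path) -> TemperatureTrace:
    df, _ = _read_csv(path, ["time_s", "temperature_K"])
    return TemperatureTrace(
        df["time_s"].to_numpy(), df["temperature_K"].to_numpy(), label=str(path)
    )


def write_temperature_csv(trace: TemperatureTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times_s, "temperature_K": trace.values_K}).to_csv(
        path, index=False
    )


def read_ratio_csv(
    path: str | Path, calibration: CalibrationParams | None = None
) -> DyeRatioTrace:
    """Read a ``time_s,nr`` file; calibration from argument or header comment."""
    df, meta = _read_csv(path, ["time_s", "nr"])
    if calibration is None:
        if "Tref_K" not in meta:
            raise ValueError(
                f"{path}: no calibration given and no '# Tref_K=...' header comment"
            )
        calibration = CalibrationParams(
            reference_temperature_K=meta["Tref_K"],
            activation_energy_kcal_per_mol=meta.get("Ea_kcal_mol", 6.55),
        )
    return DyeRatioTrace(
        df["time_s"].to_numpy(), df["nr"].to_numpy(), calibration, label=str(path)
    )


def write_ratio_csv(trace: DyeRatioTrace, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# Tref_K={trace.calibration.reference_temperature_K} "
            f"Ea_kcal_mol={trace.calibration.activation_energy_kcal_per_mol}\n"
        )
        pd.DataFrame({"time_s": trace.times_s, "nr": trace.nr}).to_csv(fh, index=False)


def read_schedule_yaml(path: str | Path) -> list[dict]:
    """Drive schedule: YAML list of {t_start_s, I_pA, eta, [label]}."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list) or not data:
        raise ConfigError(f"{path}: schedule must be a non-empty YAML list")
    for i, seg in enumerate(data):
        missing = {"t_start_s", "I_pA"} - set(seg)
        if missing:
            raise ConfigError(f"{path}: segment {i} missing keys {sorted(missing)}")
    return data
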