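"""CSV readers/writers, configuration loading, and run manifests.

Forcing and observation series travel as plain CSV with ISO-8601
timestamps; forcing files carry a ``# units:`` comment header and are
validated to be gap-free hourly on read.  The run configuration is a
single YAML file with one section per subsystem; unknown keys are
rejected so typos fail loudly, and every field has a documented default
(the dataclass defaults across the package).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .bgm import PondGeometry, _check_hourly
from .strain import StrainResponseTable, default_strain_table
from .synthetic import ScenarioConfig
from .thermal import ThermalParams
from .uncertainty import (
    ErrorModelConfig,
    StructureErrorConfig,
    VariableError,
    bgm_default_errors,
    met_default_errors,
)

__all__ = [
    "read_forcing",
    "write_forcing",
    "read_observations",
    "write_observations",
    "load_strain_table",
    "RunConfig",
    "load_config",
    "write_manifest",
    "EXIT_CONFIG_ERROR",
    "EXIT_DATA_ERROR",
]

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


# ---------------------------------------------------------------------------
# Time-series CSV
# ---------------------------------------------------------------------------


def write_forcing(
    forcing: pd.DataFrame, path, units: Optional[Dict[str, str]] = None
) -> None:
    """Write a forcing series with a units comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        if units:
            fh.write(f"# units: {json.dumps(units)}\n")
        # %.17g preserves float64 exactly, so write -> read round-trips
        forcing.rename_axis("timestamp").to_csv(fh, float_format="%.17g")


def read_forcing(path, *, require_hourly: bool = True) -> pd.DataFrame:
    """Read a forcing CSV: ISO-8601 ``timestamp`` column plus variables.

    Raises a precise error (naming the offending row or interval) for a
    missing column, an unparseable timestamp, or a cadence gap.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "timestamp" not in df.columns:
        raise ValueError(f"{path}: missing required 'timestamp' column")
    try:
        stamps = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(df["timestamp"], errors="coerce")
        bad = np.nonzero(parsed.isna().to_numpy())[0]
        row = int(bad[0]) + 2 if bad.size else "?"
        raise ValueError(f"{path}: unparseable timestamp at row {row}") from None
    df = df.drop(columns="timestamp")
    df.index = pd.DatetimeIndex(stamps, name="timestamp")
    if not df.index.is_monotonic_increasing:
        raise ValueError(f"{path}: timestamps must be strictly increasing")
    for col in df.columns:
        if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
            raise ValueError(f"{path}: non-finite values in column {col!r}")
    if require_hourly:
        _check_hourly(df.index)
    return df


def write_observations(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, index=False, float_format="%.10g")


def read_observations(path) -> pd.DataFrame:
    """Read long-format observations (timestamp, variable, value[, sd]).

    Rows are sorted per variable; duplicate (timestamp, variable) pairs
    and negative OD750 values are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"timestamp", "variable", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    dup = df.duplicated(subset=["timestamp", "variable"])
    if dup.any():
        t = df.loc[dup.idxmax(), "timestamp"]
        raise ValueError(f"{path}: duplicate (timestamp, variable) at {t}")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ValueError(f"{path}: non-finite observation values")
    od = df[df["variable"].str.lower().isin(["od750", "biomass"])]
    if (od["value"] < 0).any():
        raise ValueError(f"{path}: negative OD750 observation")
    return df.sort_values(["variable", "timestamp"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Strain table files
# ---------------------------------------------------------------------------


def load_strain_table(source) -> StrainResponseTable:
    """Build a strain table from a YAML file path or a parsed mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    if not isinstance(source, dict):
        raise ValueError("strain table source must be a mapping or a path")
    known = {
        "temperature_grid",
        "light_grid",
        "growth_surface",
        "dark_loss_surface",
        "k_a",
        "K_B",
        "K_z",
        "biomass_unit",
        "od_calibration",
    }
    unknown = set(source) - known
    if unknown:
        raise ValueError(f"unknown strain table keys: {sorted(unknown)}")
    return StrainResponseTable(**source)


def dump_strain_table(table: StrainResponseTable, path) -> None:
    data = {
        "temperature_grid": [float(v) for v in table.temperature_grid],
        "light_grid": [float(v) for v in table.light_grid],
        "growth_surface": [[float(v) for v in row] for row in table.growth_surface],
        "dark_loss_surface": [
            [float(v) for v in row] for row in table.dark_loss_surface
        ],
        "k_a": float(table.k_a),
        "K_B": float(table.K_B),
        "K_z": float(table.K_z),
        "biomass_unit": table.biomass_unit,
        "od_calibration": float(table.od_calibration),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class FilterConfig:
    """Filter selection and parameters."""

    type: str = "pfbe"  # pf | pfbe
    n_particles: int = 200
    s: float = 0.005
    bias_model: str = "adaptive"  # adaptive | persistence
    obs_od_frac_sd: float = 0.05
    obs_temp_sd_c: float = 0.2

    def __post_init__(self) -> None:
        if self.type not in ("pf", "pfbe"):
            raise ValueError(f"filter.type must be pf or pfbe, got {self.type!r}")
        if self.n_particles < 2:
            raise ValueError("filter.n_particles must be >= 2")
        if not (0.005 <= self.s <= 0.025):
            raise ValueError("filter.s must lie in [0.005, 0.025]")
        if self.bias_model not in ("adaptive", "persistence"):
            raise ValueError("filter.bias_model must be adaptive or persistence")


@dataclass
class ExperimentConfig:
    id: int = 4
    n_cycles: int = 6
    horizon_days: int = 7
    met_members: int = 11

    def __post_init__(self) -> None:
        if self.id not in (1, 2, 3, 4):
            raise ValueError("experiment.id must be 1..4")


@dataclass
class RunConfig:
    pond: PondGeometry = field(default_factory=PondGeometry)
    thermal: ThermalParams = field(default_factory=ThermalParams)
    strain: StrainResponseTable = field(default_factory=default_strain_table)
    filter: FilterConfig = field(default_factory=FilterConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    biomass_errors: ErrorModelConfig = field(default_factory=bgm_default_errors)
    met_errors: ErrorModelConfig = field(default_factory=met_default_errors)
    seed: int = 0
    output_dir: str = "pondcast_output"
    raw: Dict[str, Any] = field(default_factory=dict, repr=False)


def _build_dataclass(cls, data: Dict[str, Any], path: str):
    names = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from None


def _build_error_model(data: Dict[str, Any], path: str, default_factory):
    base = default_factory()
    allowed = {
        "variables",
        "correlation",
        "decorrelation_hours",
        "n_members",
        "s",
        "structure",
        "obs_od_frac_sd",
        "obs_temp_sd_c",
        "member_zero_unperturbed",
    }
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs: Dict[str, Any] = {}
    if "variables" in data:
        kwargs["variables"] = [
            _build_dataclass(VariableError, v, f"{path}.variables[{i}]")
            for i, v in enumerate(data["variables"])
        ]
    else:
        kwargs["variables"] = base.variables
    kwargs["correlation"] = np.asarray(data.get("correlation", base.correlation))
    if "structure" in data:
        kwargs["structure"] = _build_dataclass(
            StructureErrorConfig, data["structure"], f"{path}.structure"
        )
    else:
        kwargs["structure"] = base.structure
    for key in (
        "decorrelation_hours",
        "n_members",
        "s",
        "obs_od_frac_sd",
        "obs_temp_sd_c",
        "member_zero_unperturbed",
    ):
        kwargs[key] = data.get(key, getattr(base, key))
    try:
        return ErrorModelConfig(**kwargs)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


_SECTIONS = {
    "pond",
    "thermal",
    "strain",
    "filter",
    "experiment",
    "scenario",
    "biomass_errors",
    "met_errors",
    "seed",
    "output_dir",
}


def load_config(path=None, data: Optional[Dict[str, Any]] = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the all-defaults configuration.  Unknown sections
    or keys are rejected with a message naming the offending path.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - _SECTIONS
    if unknown:
        raise ValueError(f"config: unknown sections {sorted(unknown)}")

    cfg = RunConfig(raw=data)
    if "pond" in data:
        cfg.pond = _build_dataclass(PondGeometry, data["pond"], "pond")
    if "thermal" in data:
        cfg.thermal = _build_dataclass(ThermalParams, data["thermal"], "thermal")
    if "strain" in data:
        strain = data["strain"]
        cfg.strain = load_strain_table(strain)
    if "filter" in data:
        cfg.filter = _build_dataclass(FilterConfig, data["filter"], "filter")
    if "experiment" in data:
        cfg.experiment = _build_dataclass(
            ExperimentConfig, data["experiment"], "experiment"
        )
    if "scenario" in data:
        cfg.scenario = _build_dataclass(ScenarioConfig, data["scenario"], "scenario")
    if "biomass_errors" in data:
        cfg.biomass_errors = _build_error_model(
            data["biomass_errors"], "biomass_errors", bgm_default_errors
        )
    if "met_errors" in data:
        cfg.met_errors = _build_error_model(
            data["met_errors"], "met_errors", met_default_errors
        )
    if "seed" in data:
        cfg.seed = int(data["seed"])
    if "output_dir" in data:
        cfg.output_dir = str(data["output_dir"])
    # keep the error-model ensemble size and s in sync with the filter section
    if "filter" in data:
        for err in (cfg.biomass_errors, cfg.met_errors):
            err.n_members = cfg.filter.n_particles
            err.s = cfg.filter.s
            err.obs_od_frac_sd = cfg.filter.obs_od_frac_sd
            err.obs_temp_sd_c = cfg.filter.obs_temp_sd_c
            err.__post_init__()
    return cfg


def write_manifest(path, seed: int, config: Optional[Dict[str, Any]] = None) -> None:
    """Write the provenance manifest: seed, config hash, versions."""
    import pondcast

    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "seed": int(seed),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config or {},
        "versions": {
            "pondcast": pondcast.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
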