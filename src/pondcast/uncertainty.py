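"""Forcing perturbations and model-structure noise for the DA ensembles.

Sensor and forcing uncertainty is represented by cross-correlated normal
perturbations: additive for temperatures (SD in the variable's units),
multiplicative for fluxes/speeds (SD as a fraction of the value, factor
floored at 0.01 so large fractional SDs cannot flip the sign).  The
perturbation fields evolve in time as first-order autoregressive (AR(1))
processes with a configurable decorrelation time, so perturbed forcing
keeps its diurnal coherence while the ensemble stays dispersed.

Model-structure error is applied on top of the propagated states: a
fractional normal perturbation of the biomass state at each assimilation
cycle, and an AR(1) temperature noise with a fixed stationary SD added
hourly to the thermal ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableError",
    "StructureErrorConfig",
    "ErrorModelConfig",
    "bgm_default_errors",
    "met_default_errors",
    "CorrelatedAR1",
    "AR1Noise",
    "correlated_standard_draws",
    "perturb_forcing",
    "apply_perturbation",
    "structure_noise_bgm",
]


@dataclass(frozen=True)
class VariableError:
    """Perturbation spec for one forcing variable.

    mode is "additive" (magnitude in the variable's units) or
    "multiplicative" (magnitude as fractional SD of the value).
    ``nonnegative`` clips the perturbed values at 0.
    """

    name: str
    mode: str
    magnitude: float
    nonnegative: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if not self.magnitude >= 0:
            raise ValueError("magnitude must be >= 0")


@dataclass(frozen=True)
class StructureErrorConfig:
    """Model-structure error magnitudes.

    bgm_fraction: fractional SD applied to the biomass state at each
        assimilation cycle (0.15 = 15% of the simulated value).
    thermal_sd_c: stationary SD (degC) of the AR(1) noise added hourly to
        the thermal ensemble.
    """

    bgm_fraction: float = 0.15
    thermal_sd_c: float = 1.0


def _check_correlation(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have unit diagonal")
    # Positive definiteness via Cholesky; report the offending leading minor.
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        for k in range(1, corr.shape[0] + 1):
            if np.linalg.det(corr[:k, :k]) <= 0:
                raise ValueError(
                    f"correlation matrix is not positive definite "
                    f"(leading minor of order {k} is non-positive)"
                ) from None
        raise
    return corr


@dataclass
class ErrorModelConfig:
    """Full error-model parameterization for one DA system."""

    variables: List[VariableError]
    correlation: np.ndarray
    decorrelation_hours: float = 24.0
    n_members: int = 200
    s: float = 0.005
    structure: StructureErrorConfig = field(default_factory=StructureErrorConfig)
    obs_od_frac_sd: float = 0.05
    obs_temp_sd_c: float = 0.2
    member_zero_unperturbed: bool = False

    def __post_init__(self) -> None:
        self.correlation = _check_correlation(self.correlation)
        if self.correlation.shape[0] != len(self.variables):
            raise ValueError("correlation matrix size must match variable count")
        if not (isinstance(self.n_members, (int, np.integer)) and self.n_members >= 2):
            raise ValueError("ensemble size N must be >= 2")
        if not (0.005 <= self.s <= 0.025):
            raise ValueError("bias jitter s must lie in [0.005, 0.025]")
        if not self.decorrelation_hours > 0:
            raise ValueError("decorrelation_hours must be > 0")

    @property
    def variable_names(self) -> List[str]:
        return [v.name for v in self.variables]


def bgm_default_errors(**overrides) -> ErrorModelConfig:
    """Default biomass-DA error model: 25% multiplicative PAR error, 2 degC
    additive water-temperature error, cross-correlation 0.48."""
    kw = dict(
        variables=[
            VariableError("par", "multiplicative", 0.25, nonnegative=True),
            VariableError("water_temperature", "additive", 2.0),
        ],
        correlation=np.array([[1.0, 0.48], [0.48, 1.0]]),
    )
    kw.update(overrides)
    return ErrorModelConfig(**kw)


def met_default_errors(**overrides) -> ErrorModelConfig:
    """Default thermal-DA error model: 4 degC additive air/dewpoint errors,
    50% multiplicative shortwave/wind/pressure errors; air-dewpoint
    correlation 0.53 and air-shortwave correlation 0.44."""
    corr = np.eye(5)
    corr[0, 1] = corr[1, 0] = 0.53  # air - dewpoint
    corr[0, 2] = corr[2, 0] = 0.44  # air - shortwave
    kw = dict(
        variables=[
            VariableError("air_temperature", "additive", 4.0),
            VariableError("dewpoint", "additive", 4.0),
            VariableError("shortwave", "multiplicative", 0.5, nonnegative=True),
            VariableError("wind_speed", "multiplicative", 0.5, nonnegative=True),
            VariableError("pressure", "multiplicative", 0.5, nonnegative=True),
        ],
        correlation=corr,
    )
    kw.update(overrides)
    return ErrorModelConfig(**kw)


class CorrelatedAR1:
    """Cross-correlated standardized AR(1) perturbation fields.

    Maintains a (n_vars, n_members) state z with stationary N(0, 1)
    marginals and the requested instantaneous cross-correlation between
    variables; each step applies z <- phi z + sqrt(1 - phi^2) L eta with
    phi = exp(-dt / tau).  ``reindex`` follows particle resampling so each
    particle keeps its own forcing-error history.
    """

    def __init__(
        self,
        correlation: np.ndarray,
        n_members: int,
        decorrelation_hours: float,
        rng: np.random.Generator,
    ) -> None:
        self.correlation = _check_correlation(correlation)
        self._chol = np.linalg.cholesky(self.correlation)
        self.n_vars = self.correlation.shape[0]
        self.n_members = int(n_members)
        self.tau = float(decorrelation_hours)
        self.rng = rng
        self.z = self._chol @ rng.standard_normal((self.n_vars, self.n_members))

    def step(self, dt_hours: float = 1.0) -> np.ndarray:
        phi = np.exp(-dt_hours / self.tau)
        eta = self._chol @ self.rng.standard_normal((self.n_vars, self.n_members))
        self.z = phi * self.z + np.sqrt(1.0 - phi**2) * eta
        return self.z

    def reindex(self, idx: np.ndarray) -> None:
        self.z = self.z[:, idx]


def correlated_standard_draws(
    correlation: np.ndarray,
    n_steps: int,
    n_members: int,
    rng: np.random.Generator,
    decorrelation_hours: float = 24.0,
) -> np.ndarray:
    """Standardized perturbation fields, shape (n_steps, n_vars, n_members).

    Zero-mean, unit-variance marginals with the requested instantaneous
    cross-correlation, evolving in time as AR(1) with the configured
    decorrelation time.  Bit-reproducible for a fixed generator state.
    """
    proc = CorrelatedAR1(correlation, n_members, decorrelation_hours, rng)
    out = np.empty((n_steps, proc.n_vars, n_members))
    out[0] = proc.z
    for t in range(1, n_steps):
        out[t] = proc.step()
    return out


def apply_perturbation(
    values: np.ndarray, spec: VariableError, z: np.ndarray
) -> np.ndarray:
    """Apply one variable's perturbation given standardized draws z.

    additive: value + magnitude * z; multiplicative: value * max(1 +
    magnitude * z, 0.01).  Non-negative variables are clipped at 0.
    """
    values = np.asarray(values, dtype=float)
    if spec.mode == "additive":
        out = values + spec.magnitude * z
    else:
        factor = np.maximum(1.0 + spec.magnitude * z, 0.01)
        out = values * factor
    if spec.nonnegative:
        out = np.maximum(out, 0.0)
    return out


def perturb_forcing(
    forcing: pd.DataFrame,
    cfg: ErrorModelConfig,
    n_members: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[pd.DataFrame]:
    """Generate an ensemble of perturbed copies of a forcing series.

    Unlisted columns are passed through unchanged.  With
    ``cfg.member_zero_unperturbed`` member 0 is the input itself.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = int(n_members) if n_members is not None else cfg.n_members
    missing = [v.name for v in cfg.variables if v.name not in forcing.columns]
    if missing:
        raise ValueError(f"forcing is missing configured variables: {missing}")
    draws = correlated_standard_draws(
        cfg.correlation, len(forcing), n, rng, cfg.decorrelation_hours
    )
    members = []
    for k in range(n):
        df = forcing.copy()
        if not (cfg.member_zero_unperturbed and k == 0):
            for j, spec in enumerate(cfg.variables):
                df[spec.name] = apply_perturbation(
                    forcing[spec.name].to_numpy(dtype=float), spec, draws[:, j, k]
                )
        members.append(df)
    return members


def structure_noise_bgm(
    values: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Biomass structure error: value * (1 + fraction * zeta), clipped at 0.

    Applied to each particle at each assimilation cycle.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("biomass values must be >= 0")
    zeta = rng.standard_normal(values.shape)
    return np.maximum(values * (1.0 + fraction * zeta), 0.0)


class AR1Noise:
    """Scalar-per-member AR(1) noise with a fixed stationary SD.

    Used for the thermal model-structure error: ``step()`` returns the
    (n_members,) noise values to add for the current hour.
    """

    def __init__(
        self,
        sd: float,
        decorrelation_hours: float,
        n_members: int,
        rng: np.random.Generator,
    ) -> None:
        if sd < 0:
            raise ValueError("sd must be >= 0")
        self.sd = float(sd)
        self.tau = float(decorrelation_hours)
        self.rng = rng
        self.z = sd * rng.standard_normal(int(n_members))

    def step(self, dt_hours: float = 1.0) -> np.ndarray:
        phi = np.exp(-dt_hours / self.tau)
        eta = self.rng.standard_normal(self.z.shape)
        self.z = phi * self.z + self.sd * np.sqrt(1.0 - phi**2) * eta
        return self.z

    def reindex(self, idx: np.ndarray) -> None:
        self.z = self.z[idx]
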