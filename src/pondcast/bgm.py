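"""Layered microalgae biomass growth model for well-mixed open ponds.

The pond volume is discretized vertically into ``L`` equal layers.  Surface
PAR attenuates with depth following Beer-Lambert with a scatter-corrected
attenuation coefficient, each layer grows exponentially over a time step at
its local rate mu(T, I_j), and the pond is re-homogenized after every step
(mechanically mixed raceway).  At night the whole culture loses biomass by
dark respiration at mu_dark(T, I_avg) where I_avg is the mean layer light
of the preceding day.

All rates are specific rates in day^-1; time steps are in hours and
converted once inside the update.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .strain import StrainResponseTable, dark_loss_rate, growth_rate

__all__ = [
    "DAY_PAR_THRESHOLD",
    "PondGeometry",
    "BiomassState",
    "scatter_corrected_k",
    "light_profile",
    "day_growth_factor",
    "bgm_step",
    "daily_average_light",
    "simulate_bgm",
]

logger = logging.getLogger(__name__)

#: Surface PAR (umol m^-2 s^-1) above which a step counts as daytime.
#: Dawn/dusk light below this is photosynthetically negligible.
DAY_PAR_THRESHOLD = 1.0


@dataclass(frozen=True)
class PondGeometry:
    """Pond discretization and bulk thermal constants.

    depth:    pond operating depth d (m); raceway default 0.30 m.
    n_layers: number of equal-volume vertical layers L.
    rho:      water density (kg m^-3).
    c_v:      specific heat of water (J kg^-1 K^-1).
    """

    depth: float = 0.30
    n_layers: int = 50
    rho: float = 1000.0
    c_v: float = 4186.0

    def __post_init__(self) -> None:
        if not self.depth > 0:
            raise ValueError("depth must be > 0")
        if not (isinstance(self.n_layers, (int, np.integer)) and self.n_layers >= 1):
            raise ValueError("n_layers must be a positive integer")
        if not (self.rho > 0 and self.c_v > 0):
            raise ValueError("rho and c_v must be > 0")

    @property
    def layer_thickness(self) -> float:
        return self.depth / self.n_layers

    @property
    def layer_midpoints(self) -> np.ndarray:
        """Depths z_j = (j - 1/2) * dz of layer midpoints, j = 1..L."""
        dz = self.layer_thickness
        return (np.arange(self.n_layers) + 0.5) * dz


@dataclass(frozen=True)
class BiomassState:
    """Well-mixed biomass concentration plus nighttime-loss bookkeeping."""

    B: float
    timestamp: Optional[pd.Timestamp] = None
    I_avg_prev_day: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.B) and self.B >= 0):
            raise ValueError("biomass B must be finite and >= 0")
        if not (np.isfinite(self.I_avg_prev_day) and self.I_avg_prev_day >= 0):
            raise ValueError("I_avg_prev_day must be finite and >= 0")


def scatter_corrected_k(table: StrainResponseTable, B, z):
    """Scatter-corrected biomass light attenuation coefficient.

    k_sca = k_a * K_B/(K_B + B) * K_z/(K_z + z); always in (0, k_a], with
    equality only at B = z = 0.  Accepts arrays for B and z (broadcast).
    """
    B = np.asarray(B, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(B < 0) or np.any(z < 0):
        raise ValueError("B and z must be >= 0")
    out = table.k_a * (table.K_B / (table.K_B + B)) * (table.K_z / (table.K_z + z))
    return float(out) if out.ndim == 0 else out


def light_profile(I0, B, geom: PondGeometry, table: StrainResponseTable):
    """PAR at each layer midpoint: I_j = I0 * exp(-k_sca(B, z_j) * B * z_j).

    ``I0`` and ``B`` may be arrays (broadcast against each other); the layer
    axis is appended last, so the result has shape ``(..., n_layers)``.
    """
    I0 = np.asarray(I0, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(I0 < 0):
        raise ValueError("surface PAR I0 must be >= 0")
    z = geom.layer_midpoints
    Bx = B[..., np.newaxis]
    k = scatter_corrected_k(table, Bx, z)
    return I0[..., np.newaxis] * np.exp(-k * Bx * z)


def day_growth_factor(
    B,
    T,
    I0,
    dt_hours: float,
    table: StrainResponseTable,
    geom: PondGeometry,
) -> Tuple[np.ndarray, np.ndarray]:
    """Daytime multiplicative update factor and layer-mean light.

    Each layer grows exponentially at mu_j = mu(T, I_j) over dt, then the
    pond is re-homogenized, so B' = B * (1/L) * sum_j exp(mu_j * dt_days).
    Returns ``(factor, layer_mean_light)``; both vectorized over particles.
    """
    profiles = light_profile(I0, B, geom, table)  # (..., L)
    T = np.asarray(T, dtype=float)
    mu = growth_rate(table, T[..., np.newaxis], profiles)
    factor = np.mean(np.exp(np.asarray(mu) * dt_hours / 24.0), axis=-1)
    return factor, profiles.mean(axis=-1)


def bgm_step(
    state: BiomassState,
    T: float,
    I0: float,
    dt_hours: float,
    table: StrainResponseTable,
    geom: PondGeometry,
) -> BiomassState:
    """Advance the biomass state over one interval of constant forcing.

    Daytime (I0 above :data:`DAY_PAR_THRESHOLD`): per-layer exponential
    growth followed by instantaneous re-homogenization.  Night: uniform
    exponential dark loss at mu_dark(T, I_avg of the preceding day).
    ``I_avg_prev_day`` bookkeeping is handled by the caller/driver.
    """
    if not dt_hours > 0:
        raise ValueError("dt_hours must be > 0")
    if I0 > DAY_PAR_THRESHOLD:
        factor, _ = day_growth_factor(state.B, T, I0, dt_hours, table, geom)
        B_new = state.B * float(factor)
    else:
        mu_dark = dark_loss_rate(table, T, state.I_avg_prev_day)
        B_new = state.B * float(np.exp(mu_dark * dt_hours / 24.0))
    return replace(state, B=B_new)


def daily_average_light(profiles) -> float:
    """Mean PAR over all daytime steps and all layers of one day.

    ``profiles`` is a sequence of per-layer PAR arrays (one per daytime
    step).  An empty window returns 0 with a warning.
    """
    if len(profiles) == 0:
        logger.warning("daily_average_light: empty daytime window, returning 0")
        return 0.0
    return float(np.mean([np.mean(p) for p in profiles]))


def _check_hourly(index: pd.DatetimeIndex) -> None:
    if len(index) < 2:
        return
    deltas = np.diff(index.values).astype("timedelta64[s]").astype(float)
    bad = np.nonzero(deltas != 3600.0)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"forcing must be gap-free hourly; interval {index[i]} -> "
            f"{index[i + 1]} is {deltas[i] / 3600.0:g} h"
        )


def simulate_bgm(
    forcing: pd.DataFrame,
    B0: float,
    table: StrainResponseTable,
    geom: PondGeometry,
    *,
    par_col: str = "par",
    temp_col: str = "water_temperature",
    I_avg_init: float = 0.0,
    return_state: bool = False,
):
    """Hourly open-loop biomass trajectory driven by (T, PAR) forcing.

    The previous-day mean light used for dark respiration is rolled at
    each day-to-night transition.  Before any daytime data, dark loss uses
    I_avg = ``I_avg_init`` (default 0, the table's dark column).

    Returns the trajectory as a Series indexed like ``forcing`` (the value
    at each timestamp is the state *after* that hour's update), or a
    ``(series, final_state)`` pair when ``return_state`` is set.
    """
    for col in (par_col, temp_col):
        if col not in forcing.columns:
            raise ValueError(f"forcing is missing required column {col!r}")
    _check_hourly(forcing.index)

    B = float(B0)
    I_avg = float(I_avg_init)
    day_profile_means: list[float] = []
    was_day = False
    out = np.empty(len(forcing))

    par = forcing[par_col].to_numpy(dtype=float)
    temp = forcing[temp_col].to_numpy(dtype=float)
    for i in range(len(forcing)):
        I0, T = par[i], temp[i]
        is_day = I0 > DAY_PAR_THRESHOLD
        if is_day:
            if not was_day:
                day_profile_means.clear()
            factor, layer_mean = day_growth_factor(B, T, I0, 1.0, table, geom)
            B *= float(factor)
            day_profile_means.append(float(layer_mean))
        else:
            if was_day and day_profile_means:
                I_avg = float(np.mean(day_profile_means))
            B *= float(np.exp(dark_loss_rate(table, T, I_avg) / 24.0))
        was_day = is_day
        out[i] = B

    series = pd.Series(out, index=forcing.index, name="biomass")
    if return_state:
        if was_day and day_profile_means:
            I_avg = float(np.mean(day_profile_means))
        state = BiomassState(B=B, timestamp=forcing.index[-1], I_avg_prev_day=I_avg)
        return series, state
    return series
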