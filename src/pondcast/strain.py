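"""Strain-specific growth and dark-loss response surfaces.

A microalgae strain responds to the combination of water temperature and
photosynthetically active radiation (PAR) with a specific growth rate
``mu = f(T, I)`` (day^-1), measured in laboratory cultures over a grid of
(temperature, light) conditions.  At night the culture loses biomass by dark
respiration at a rate ``mu_dark = f(T, I_avg)`` that depends on temperature
and on the mean light experienced during the preceding day.  Both surfaces,
together with the light-attenuation coefficients of the culture, are the
strain parameterization consumed by the growth model.

Queries between measured grid nodes are answered by bilinear interpolation;
queries outside the grid are clamped to the nearest edge, so the surfaces
are defined (and bounded by measured values) everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "StrainResponseTable",
    "growth_rate",
    "dark_loss_rate",
    "default_strain_table",
]


def _as_grid(values: Any, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"{name} must be a 1-D grid with at least two points")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if not np.all(np.diff(arr) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    return arr


@dataclass
class StrainResponseTable:
    """Gridded mu(T, I) and mu_dark(T, I_avg) surfaces plus optics.

    Parameters
    ----------
    temperature_grid
        Water temperatures (degC), strictly increasing.
    light_grid
        PAR intensities (umol photons m^-2 s^-1), strictly increasing and
        containing 0 so the dark column is always defined.
    growth_surface
        Specific growth rates mu (day^-1), shape
        ``(len(temperature_grid), len(light_grid))``.
    dark_loss_surface
        Dark specific rates mu_dark (day^-1), same shape, <= 0 everywhere;
        the light axis is the preceding-day average PAR.
    k_a
        Biomass light absorption coefficient over the PAR band
        (m^2 per biomass unit per m, i.e. attenuation per unit biomass
        concentration per metre).
    K_B, K_z
        Scattering half-saturation constants in biomass units and metres.
    biomass_unit
        Declared unit of the biomass state ("od750" or "g_afdw_m3").
    od_calibration
        Linear factor c with OD750 = c * B; identity when the state is
        already carried in OD750-equivalent units.
    """

    temperature_grid: np.ndarray
    light_grid: np.ndarray
    growth_surface: np.ndarray
    dark_loss_surface: np.ndarray
    k_a: float
    K_B: float
    K_z: float
    biomass_unit: str = "od750"
    od_calibration: float = 1.0
    _growth_interp: RegularGridInterpolator = field(init=False, repr=False)
    _dark_interp: RegularGridInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.temperature_grid = _as_grid(self.temperature_grid, "temperature_grid")
        self.light_grid = _as_grid(self.light_grid, "light_grid")
        if not np.any(self.light_grid == 0.0):
            raise ValueError("light_grid must include 0 (the dark column)")
        shape = (self.temperature_grid.size, self.light_grid.size)
        self.growth_surface = np.asarray(self.growth_surface, dtype=float)
        self.dark_loss_surface = np.asarray(self.dark_loss_surface, dtype=float)
        for name, surf in (
            ("growth_surface", self.growth_surface),
            ("dark_loss_surface", self.dark_loss_surface),
        ):
            if surf.shape != shape:
                raise ValueError(
                    f"{name} has shape {surf.shape}, expected {shape} "
                    "(temperature x light)"
                )
            if not np.all(np.isfinite(surf)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.dark_loss_surface > 0):
            raise ValueError("dark_loss_surface must be <= 0 everywhere")
        for name in ("k_a", "K_B", "K_z", "od_calibration"):
            if not (float(getattr(self, name)) > 0):
                raise ValueError(f"{name} must be > 0")
        self._growth_interp = RegularGridInterpolator(
            (self.temperature_grid, self.light_grid), self.growth_surface
        )
        self._dark_interp = RegularGridInterpolator(
            (self.temperature_grid, self.light_grid), self.dark_loss_surface
        )

    def scaled(self, growth_factor: float) -> "StrainResponseTable":
        """Return a copy with both rate surfaces scaled by ``growth_factor``.

        Used to build a "truth" strain table that grows slower (or faster)
        than the nominal laboratory parameterization in twin experiments.
        """
        return replace(
            self,
            growth_surface=self.growth_surface * growth_factor,
            dark_loss_surface=self.dark_loss_surface * growth_factor,
        )


def _query(table: StrainResponseTable, interp: RegularGridInterpolator, T, I):
    T = np.asarray(T, dtype=float)
    I = np.asarray(I, dtype=float)
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(I))):
        raise ValueError("temperature and light queries must be finite")
    if np.any(I < 0):
        raise ValueError("light intensity must be >= 0")
    # Edge clamping: queries outside the measured grid take the edge value.
    scalar_input = T.ndim == 0 and I.ndim == 0
    Tc = np.clip(T, table.temperature_grid[0], table.temperature_grid[-1])
    Ic = np.clip(I, table.light_grid[0], table.light_grid[-1])
    pts = np.stack(np.broadcast_arrays(Tc, Ic), axis=-1)
    out = interp(pts)
    if scalar_input:
        return float(out.reshape(()))
    return out


def growth_rate(table: StrainResponseTable, T, I):
    """Specific growth rate mu(T, I) in day^-1 by bilinear interpolation.

    Accepts scalars or broadcastable arrays; exact at grid nodes, clamped
    to the nearest edge outside the grid.
    """
    return _query(table, table._growth_interp, T, I)


def dark_loss_rate(table: StrainResponseTable, T, I_avg):
    """Dark respiration rate mu_dark(T, I_avg) in day^-1 (<= 0)."""
    return _query(table, table._dark_interp, T, I_avg)


def default_strain_table() -> StrainResponseTable:
    """A plausible synthetic freshwater-chlorophyte response table.

    The growth surface is a light-saturating (half-saturation 100 umol m^-2
    s^-1), temperature-optimal (optimum 30 degC) response tabulated on a
    coarse laboratory-style grid, peaking near 2.2 day^-1.  Dark loss grows
    mildly with temperature and with the preceding day's light.  Attenuation
    constants are set so that a culture near OD750 ~ 1 in a 0.3 m pond is
    strongly light-limited at depth, which is characteristic of dense
    raceway cultures.  This is a synthetic stand-in table, not a published
    laboratory parameterization.
    """
    T_grid = np.array([5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0])
    I_grid = np.array([0.0, 50.0, 100.0, 250.0, 500.0, 1000.0, 2000.0])
    TT, II = np.meshgrid(T_grid, I_grid, indexing="ij")
    mu_max = 2.2
    temp_resp = np.exp(-(((TT - 30.0) / 8.0) ** 2))
    light_resp = II / (II + 100.0)
    growth = mu_max * temp_resp * light_resp
    dark = -(0.02 + 0.04 * (TT / 30.0)) * (0.4 + 0.6 * II / (II + 300.0))
    dark = np.minimum(dark, 0.0)
    return StrainResponseTable(
        temperature_grid=T_grid,
        light_grid=I_grid,
        growth_surface=growth,
        dark_loss_surface=dark,
        k_a=40.0,
        K_B=2.0,
        K_z=0.3,
        biomass_unit="od750",
        od_calibration=1.0,
    )
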