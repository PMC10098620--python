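"""Well-mixed pond water temperature model.

A mechanically mixed raceway pond is treated as a single control volume:
the energy balance reduces to storage driven by the net surface heat flux,

    dT/dt = H_net / (rho * c_v * d),

with H_net = H_s + H_a - (H_b + H_e + H_c): net solar shortwave, net
atmospheric longwave, longwave back radiation, latent, and sensible flux.
Classical shallow-water-body formulations are used for the components
(Brunt atmospheric emissivity, Magnus saturation vapour pressure, quadratic
wind function, Bowen-ratio sensible flux); every constant is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .bgm import PondGeometry, _check_hourly

__all__ = [
    "STEFAN_BOLTZMANN",
    "ThermalParams",
    "MeteoRecord",
    "HeatFluxBreakdown",
    "saturation_vapor_pressure",
    "surface_heat_flux",
    "thermal_step",
    "simulate_pond_temperature",
    "equilibrium_temperature",
]

STEFAN_BOLTZMANN = 5.670374419e-8  # W m^-2 K^-4

#: Sanity band for simulated pond temperature (degC).
TEMP_SANITY_BAND = (-5.0, 60.0)


@dataclass(frozen=True)
class ThermalParams:
    """Surface heat-flux constants (all config-overridable).

    shortwave_albedo:      water surface reflectance for shortwave r_s.
    longwave_reflectance:  water surface reflectance for longwave r_l.
    brunt_a, brunt_b:      Brunt clear-sky emissivity e = a + b * sqrt(e_a)
                           with vapour pressure e_a in hPa.
    water_emissivity:      emissivity of the water surface.
    wind_c0, wind_c1:      evaporative wind function f(W) = c0 + c1 * W^2
                           (W m^-2 hPa^-1 with wind W in m s^-1).
    bowen_gamma:           Bowen-ratio coefficient gamma (hPa K^-1 scale).
    flux_offset:           extra flux (W m^-2) added to H_net in the time
                           step; used to inject a structural model error in
                           twin experiments (0 for the nominal model).
    """

    shortwave_albedo: float = 0.06
    longwave_reflectance: float = 0.03
    brunt_a: float = 0.60
    brunt_b: float = 0.031
    water_emissivity: float = 0.97
    wind_c0: float = 9.2
    wind_c1: float = 0.46
    bowen_gamma: float = 0.61
    flux_offset: float = 0.0


@dataclass(frozen=True)
class MeteoRecord:
    """One meteorological record; fields may be floats or aligned arrays."""

    air_temperature: object  # degC
    dewpoint: object  # degC
    wind_speed: object  # m s^-1
    pressure: object  # hPa
    shortwave: object  # W m^-2

    def __post_init__(self) -> None:
        sw = np.asarray(self.shortwave, dtype=float)
        w = np.asarray(self.wind_speed, dtype=float)
        p = np.asarray(self.pressure, dtype=float)
        if np.any(sw < 0):
            raise ValueError("shortwave must be >= 0")
        if np.any(w < 0):
            raise ValueError("wind_speed must be >= 0")
        if np.any((p <= 800.0) | (p >= 1100.0)):
            raise ValueError("pressure must lie in (800, 1100) hPa")


@dataclass(frozen=True)
class HeatFluxBreakdown:
    """Component fluxes (W m^-2); sign convention: losses are positive
    in h_b, h_e, h_c and subtracted in the net."""

    h_s: object
    h_a: object
    h_b: object
    h_e: object
    h_c: object

    @property
    def h_net(self):
        return self.h_s + self.h_a - (self.h_b + self.h_e + self.h_c)


def saturation_vapor_pressure(T):
    """Magnus saturation vapour pressure (hPa) over water at T (degC)."""
    T = np.asarray(T, dtype=float)
    out = 6.112 * np.exp(17.62 * T / (243.12 + T))
    return float(out) if out.ndim == 0 else out


def surface_heat_flux(
    T_w, met: MeteoRecord, params: ThermalParams = ThermalParams()
) -> HeatFluxBreakdown:
    """Evaluate the five surface heat-flux components at water temp T_w.

    The latent flux may be negative (condensation) and is not clipped.
    Vectorizes over arrays in ``T_w`` and the meteorological fields.
    """
    T_w = np.asarray(T_w, dtype=float)
    T_a = np.asarray(met.air_temperature, dtype=float)
    e_a = saturation_vapor_pressure(met.dewpoint)  # actual vapour pressure
    e_s = saturation_vapor_pressure(T_w)  # saturation at water temp
    W = np.asarray(met.wind_speed, dtype=float)
    p = np.asarray(met.pressure, dtype=float)

    h_s = (1.0 - params.shortwave_albedo) * np.asarray(met.shortwave, dtype=float)
    eps_atm = params.brunt_a + params.brunt_b * np.sqrt(e_a)
    h_a = (
        (1.0 - params.longwave_reflectance)
        * eps_atm
        * STEFAN_BOLTZMANN
        * (T_a + 273.15) ** 4
    )
    h_b = params.water_emissivity * STEFAN_BOLTZMANN * (T_w + 273.15) ** 4
    f_wind = params.wind_c0 + params.wind_c1 * W**2
    h_e = f_wind * (e_s - e_a)
    h_c = params.bowen_gamma * (p / 1000.0) * f_wind * (T_w - T_a)
    return HeatFluxBreakdown(h_s=h_s, h_a=h_a, h_b=h_b, h_e=h_e, h_c=h_c)


@dataclass(frozen=True)
class WaterTempState:
    T_w: float
    timestamp: Optional[pd.Timestamp] = None


def thermal_step(
    state: WaterTempState,
    met: MeteoRecord,
    geom: PondGeometry,
    dt_seconds: float,
    params: ThermalParams = ThermalParams(),
) -> WaterTempState:
    """Explicit storage update T' = T + H_net * dt / (rho * c_v * d)."""
    if not dt_seconds > 0:
        raise ValueError("dt_seconds must be > 0")
    h_net = surface_heat_flux(state.T_w, met, params).h_net + params.flux_offset
    T_new = state.T_w + float(h_net) * dt_seconds / (geom.rho * geom.c_v * geom.depth)
    lo, hi = TEMP_SANITY_BAND
    if not (lo < T_new < hi):
        raise ValueError(
            f"water temperature {T_new:.2f} degC outside sanity band "
            f"{TEMP_SANITY_BAND} at {state.timestamp}"
        )
    return WaterTempState(T_w=T_new, timestamp=state.timestamp)


def step_temperature_array(
    T_w: np.ndarray,
    met: MeteoRecord,
    geom: PondGeometry,
    dt_seconds: float,
    params: ThermalParams = ThermalParams(),
    substeps: int = 6,
) -> np.ndarray:
    """Vectorized sub-stepped update of an ensemble of temperatures."""
    T = np.array(T_w, dtype=float)
    dt = dt_seconds / substeps
    denom = geom.rho * geom.c_v * geom.depth
    for _ in range(substeps):
        h_net = surface_heat_flux(T, met, params).h_net + params.flux_offset
        T = T + np.asarray(h_net) * dt / denom
    return T


def simulate_pond_temperature(
    forcing: pd.DataFrame,
    T0: float,
    geom: PondGeometry = PondGeometry(),
    params: ThermalParams = ThermalParams(),
    *,
    substeps: int = 6,
) -> pd.Series:
    """Hourly pond temperature trajectory from gap-free meteorology.

    Each hour is integrated with ``substeps`` explicit sub-steps (default
    6/hour) to keep the 30 cm water column stable; refinement beyond this
    changes the trajectory by well under 0.05 degC on diurnal forcing.
    Columns required: air_temperature, dewpoint, wind_speed, pressure,
    shortwave.  The value at each timestamp is the state after that hour.
    """
    required = ["air_temperature", "dewpoint", "wind_speed", "pressure", "shortwave"]
    for col in required:
        if col not in forcing.columns:
            raise ValueError(f"forcing is missing required column {col!r}")
    _check_hourly(forcing.index)
    cols = {c: forcing[c].to_numpy(dtype=float) for c in required}
    T = float(T0)
    out = np.empty(len(forcing))
    lo, hi = TEMP_SANITY_BAND
    for i in range(len(forcing)):
        met = MeteoRecord(
            air_temperature=cols["air_temperature"][i],
            dewpoint=cols["dewpoint"][i],
            wind_speed=cols["wind_speed"][i],
            pressure=cols["pressure"][i],
            shortwave=cols["shortwave"][i],
        )
        T = float(step_temperature_array(T, met, geom, 3600.0, params, substeps))
        if not (lo < T < hi):
            raise ValueError(
                f"water temperature {T:.2f} degC outside sanity band at "
                f"{forcing.index[i]}"
            )
        out[i] = T
    return pd.Series(out, index=forcing.index, name="water_temperature")


def equilibrium_temperature(
    met: MeteoRecord,
    params: ThermalParams = ThermalParams(),
    bracket=(-5.0, 60.0),
) -> float:
    """Root of H_net(T_w) + flux_offset = 0 for constant meteorology."""
    from scipy.optimize import brentq

    def f(T):
        return float(surface_heat_flux(T, met, params).h_net) + params.flux_offset

    return float(brentq(f, *bracket))
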