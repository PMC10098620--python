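"""Synthetic twin-experiment data: weather, pond truth, observations, and
biased ensemble weather forecasts.

The generator emulates the inputs an operational pond-forecasting site
would have: a local weather station record (diurnal shortwave, air and dew
point temperature, wind, pressure, and PAR derived from shortwave), an
on-site truth pond simulated with a *perturbed* model (slower-growing
strain table and an extra surface heat flux), noisy observations of the
truth (hourly water temperature; OD750 at scheduled clock hours), and an
11-member ensemble weather forecast with systematic biases (cold air
temperature, high wind) and lead-growing spread.

Because the truth pond uses a strain table scaled by ``growth_scale`` < 1,
the forecaster's nominal table systematically over-predicts growth - the
recoverable bias signal the bias-aware filter is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .bgm import PondGeometry, simulate_bgm
from .strain import StrainResponseTable, default_strain_table
from .thermal import MeteoRecord, ThermalParams, equilibrium_temperature, simulate_pond_temperature

__all__ = [
    "ScenarioConfig",
    "MetForecastEnsemble",
    "Scenario",
    "generate_weather",
    "generate_truth_and_observations",
    "generate_met_forecast_ensemble",
    "generate_scenario",
]

MET_VARIABLES = ("air_temperature", "dewpoint", "wind_speed", "pressure", "shortwave")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic twin scenario."""

    duration_days: int = 14
    start: str = "2021-06-28 00:00"
    # weather climatology (mid-summer Central Valley-like)
    shortwave_peak: float = 950.0  # clear-sky noon peak, W m^-2
    shortwave_day_variability: float = 0.10  # day-to-day multiplicative SD
    sunrise_hour: float = 6.0
    sunset_hour: float = 20.0
    air_temp_mean: float = 26.0
    air_temp_amplitude: float = 8.0
    air_temp_max_hour: float = 15.0  # daily max ~2 h after solar noon
    air_temp_noise_sd: float = 0.8
    dewpoint_mean: float = 11.0
    dewpoint_noise_sd: float = 0.8
    wind_mean: float = 2.0
    wind_amplitude: float = 1.0
    wind_max_hour: float = 16.0
    wind_noise_sd: float = 0.4
    pressure_mean: float = 1008.0
    pressure_noise_sd: float = 1.0
    par_umol_per_joule: float = 2.1  # SW (W m^-2) -> PAR (umol m^-2 s^-1)
    # truth-model bias injection
    growth_scale: float = 0.8
    #: extra surface flux (W m^-2) on the truth pond; negative = extra heat
    #: loss (a bed-conduction-like process the forecast model omits), so the
    #: open-loop model runs warm against the truth pond.
    thermal_flux_offset: float = -40.0
    # observation schedule and noise
    biomass_obs_hours: Tuple[int, ...] = (16,)
    biomass_obs_frac_sd: float = 0.05
    temp_obs_sd: float = 0.2
    initial_biomass: float = 0.10  # OD750
    # ensemble weather forecast
    met_members: int = 11
    horizon_days: int = 7
    air_temp_forecast_bias: float = -2.0  # cold bias, degC
    wind_forecast_bias: float = 0.5  # positive bias, m s^-1
    forecast_spread_growth: float = 0.3  # fractional SD growth per day
    forecast_sd_air: float = 1.0  # additive base SDs at lead ~0
    forecast_sd_dewpoint: float = 1.0
    forecast_sd_wind: float = 0.4
    forecast_sd_pressure: float = 1.0
    forecast_sd_shortwave_frac: float = 0.08  # multiplicative
    forecast_error_decorrelation_hours: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_days < 2:
            raise ValueError("duration_days must be >= 2")
        if self.met_members < 2:
            raise ValueError("met_members must be >= 2")
        for name in (
            "shortwave_day_variability",
            "air_temp_noise_sd",
            "biomass_obs_frac_sd",
            "temp_obs_sd",
            "forecast_spread_growth",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class MetForecastEnsemble:
    """Member-indexed hourly weather forecast from one initialization."""

    init_time: pd.Timestamp
    index: pd.DatetimeIndex
    variables: Dict[str, np.ndarray]  # name -> (n_hours, n_members)

    @property
    def n_members(self) -> int:
        return next(iter(self.variables.values())).shape[1]

    def member_frame(self, k: int) -> pd.DataFrame:
        return pd.DataFrame(
            {name: arr[:, k] for name, arr in self.variables.items()},
            index=self.index,
        )


def _diurnal(hours: np.ndarray, mean: float, amplitude: float, max_hour: float):
    return mean + amplitude * np.cos(2.0 * np.pi * (hours - max_hour) / 24.0)


def _smooth_noise(
    n: int, sd: float, rng: np.random.Generator, tau_hours: float = 6.0
) -> np.ndarray:
    """Stationary AR(1) noise so weather wiggles stay hour-to-hour coherent."""
    if sd == 0:
        return np.zeros(n)
    phi = np.exp(-1.0 / tau_hours)
    out = np.empty(n)
    out[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + np.sqrt(1 - phi**2) * innov[i - 1]
    return sd * out


def generate_weather(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Hourly truth meteorology plus derived PAR.

    Shortwave is a clear-sky half-sine between sunrise and sunset with
    day-to-day multiplicative variability; air temperature is a sinusoid
    whose daily maximum lags solar noon; dewpoint is kept at or below the
    air temperature; PAR = ``par_umol_per_joule`` * shortwave.
    """
    n = cfg.duration_days * 24
    index = pd.date_range(cfg.start, periods=n, freq="h")
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    day = np.arange(n) // 24

    day_factor = np.maximum(
        1.0 + cfg.shortwave_day_variability * rng.standard_normal(cfg.duration_days),
        0.3,
    )
    daylen = cfg.sunset_hour - cfg.sunrise_hour
    solar = np.sin(np.pi * (hour - cfg.sunrise_hour) / daylen)
    shortwave = cfg.shortwave_peak * day_factor[day] * np.clip(solar, 0.0, None)
    shortwave[(hour < cfg.sunrise_hour) | (hour > cfg.sunset_hour)] = 0.0

    air = _diurnal(hour, cfg.air_temp_mean, cfg.air_temp_amplitude, cfg.air_temp_max_hour)
    air = air + _smooth_noise(n, cfg.air_temp_noise_sd, rng)
    dew = cfg.dewpoint_mean + _smooth_noise(n, cfg.dewpoint_noise_sd, rng)
    dew = np.minimum(dew, air - 0.5)
    wind = _diurnal(hour, cfg.wind_mean, cfg.wind_amplitude, cfg.wind_max_hour)
    wind = np.maximum(wind + _smooth_noise(n, cfg.wind_noise_sd, rng), 0.0)
    pressure = cfg.pressure_mean + _smooth_noise(n, cfg.pressure_noise_sd, rng)

    return pd.DataFrame(
        {
            "air_temperature": air,
            "dewpoint": dew,
            "wind_speed": wind,
            "pressure": pressure,
            "shortwave": shortwave,
            "par": cfg.par_umol_per_joule * shortwave,
        },
        index=index,
    )


def generate_truth_and_observations(
    cfg: ScenarioConfig,
    weather: pd.DataFrame,
    strain: StrainResponseTable,
    geom: PondGeometry,
    rng: np.random.Generator,
):
    """Simulate the truth pond and observe it with independent noise.

    The truth pond runs the *perturbed* model: strain table scaled by
    ``growth_scale`` and surface flux offset ``thermal_flux_offset``.
    Returns (truth_temperature, truth_biomass, observations) where
    observations is a long-format frame (timestamp, variable, value).
    """
    truth_table = strain.scaled(cfg.growth_scale)
    truth_params = ThermalParams(flux_offset=cfg.thermal_flux_offset)
    first_met = MeteoRecord(
        air_temperature=float(weather["air_temperature"].iloc[0]),
        dewpoint=float(weather["dewpoint"].iloc[0]),
        wind_speed=float(weather["wind_speed"].iloc[0]),
        pressure=float(weather["pressure"].iloc[0]),
        shortwave=float(weather["shortwave"].iloc[0]),
    )
    T0 = equilibrium_temperature(first_met, truth_params)
    truth_temperature = simulate_pond_temperature(weather, T0, geom, truth_params)

    truth_forcing = pd.DataFrame(
        {"par": weather["par"], "water_temperature": truth_temperature}
    )
    truth_biomass = simulate_bgm(
        truth_forcing, cfg.initial_biomass, truth_table, geom
    )

    temp_noise = cfg.temp_obs_sd * rng.standard_normal(len(truth_temperature))
    temp_obs = truth_temperature + temp_noise
    rows = [
        {"timestamp": t, "variable": "water_temperature", "value": float(v)}
        for t, v in temp_obs.items()
    ]
    bio_mask = truth_biomass.index.hour.isin(cfg.biomass_obs_hours)
    bio_truth = truth_biomass[bio_mask]
    bio_obs = np.maximum(
        bio_truth * (1.0 + cfg.biomass_obs_frac_sd * rng.standard_normal(len(bio_truth))),
        0.0,
    )
    rows += [
        {"timestamp": t, "variable": "od750", "value": float(v)}
        for t, v in bio_obs.items()
    ]
    observations = (
        pd.DataFrame(rows).sort_values(["variable", "timestamp"]).reset_index(drop=True)
    )
    return truth_temperature, truth_biomass, observations


def generate_met_forecast_ensemble(
    cfg: ScenarioConfig,
    weather: pd.DataFrame,
    init_time: pd.Timestamp,
    rng: np.random.Generator,
) -> MetForecastEnsemble:
    """Biased, lead-dispersing ensemble forecast built around truth weather.

    member = truth + systematic offset + AR(1) error whose SD grows
    linearly with lead time; member 0 is the control (offset only, no
    random error).  Shortwave errors are multiplicative so nights stay
    dark; PAR is rederived from member shortwave.
    """
    init_time = pd.Timestamp(init_time)
    horizon = cfg.horizon_days * 24
    index = pd.date_range(init_time, periods=horizon + 1, freq="h")[1:]
    if index[-1] not in weather.index:
        raise ValueError(
            f"truth weather ends {weather.index[-1]} but forecast from "
            f"{init_time} needs coverage to {index[-1]}"
        )
    truth = weather.loc[index]
    m = cfg.met_members
    lead_days = (np.arange(1, horizon + 1)) / 24.0
    growth = 1.0 + cfg.forecast_spread_growth * lead_days  # (H,)

    phi = np.exp(-1.0 / cfg.forecast_error_decorrelation_hours)

    def ar1_field(n_members: int) -> np.ndarray:
        out = np.empty((horizon, n_members))
        out[0] = rng.standard_normal(n_members)
        for t in range(1, horizon):
            out[t] = phi * out[t - 1] + np.sqrt(1 - phi**2) * rng.standard_normal(
                n_members
            )
        return out

    base_sd = {
        "air_temperature": cfg.forecast_sd_air,
        "dewpoint": cfg.forecast_sd_dewpoint,
        "wind_speed": cfg.forecast_sd_wind,
        "pressure": cfg.forecast_sd_pressure,
    }
    offsets = {
        "air_temperature": cfg.air_temp_forecast_bias,
        "wind_speed": cfg.wind_forecast_bias,
    }
    variables: Dict[str, np.ndarray] = {}
    for name in ("air_temperature", "dewpoint", "wind_speed", "pressure"):
        err = ar1_field(m) * (base_sd[name] * growth)[:, None]
        err[:, 0] = 0.0  # control member
        variables[name] = (
            truth[name].to_numpy()[:, None] + offsets.get(name, 0.0) + err
        )
    sw_err = ar1_field(m) * (cfg.forecast_sd_shortwave_frac * growth)[:, None]
    sw_err[:, 0] = 0.0
    variables["shortwave"] = truth["shortwave"].to_numpy()[:, None] * np.maximum(
        1.0 + sw_err, 0.05
    )

    variables["wind_speed"] = np.maximum(variables["wind_speed"], 0.0)
    variables["pressure"] = np.clip(variables["pressure"], 801.0, 1099.0)
    variables["dewpoint"] = np.minimum(
        variables["dewpoint"], variables["air_temperature"] - 0.1
    )
    variables["par"] = cfg.par_umol_per_joule * variables["shortwave"]
    return MetForecastEnsemble(init_time=init_time, index=index, variables=variables)


@dataclass
class Scenario:
    """A complete generated twin scenario plus lazy forecast access."""

    config: ScenarioConfig
    geometry: PondGeometry
    model_thermal: ThermalParams
    truth_thermal: ThermalParams
    forecaster_table: StrainResponseTable
    truth_table: StrainResponseTable
    weather: pd.DataFrame
    truth_temperature: pd.Series
    truth_biomass: pd.Series
    observations: pd.DataFrame
    model_forcing: pd.DataFrame
    _forecast_entropy: int = 0
    _forecast_cache: Dict[pd.Timestamp, MetForecastEnsemble] = field(
        default_factory=dict, repr=False
    )

    def series_observations(self, variable: str) -> pd.Series:
        df = self.observations[self.observations["variable"] == variable]
        return pd.Series(
            df["value"].to_numpy(), index=pd.DatetimeIndex(df["timestamp"]), name=variable
        )

    def biomass_observations(self) -> pd.Series:
        return self.series_observations("od750")

    def temperature_observations(self) -> pd.Series:
        return self.series_observations("water_temperature")

    def met_forecast(self, init_time) -> MetForecastEnsemble:
        """Deterministic per-initialization forecast (seeded by scenario
        entropy and the hour offset, so repeated calls are identical)."""
        init_time = pd.Timestamp(init_time)
        if init_time not in self._forecast_cache:
            offset = int(
                (init_time - self.weather.index[0]) / pd.Timedelta(hours=1)
            )
            rng = np.random.default_rng([self._forecast_entropy, offset])
            self._forecast_cache[init_time] = generate_met_forecast_ensemble(
                self.config, self.weather, init_time, rng
            )
        return self._forecast_cache[init_time]


def generate_scenario(
    cfg: Optional[ScenarioConfig] = None,
    seed: Optional[int] = None,
    strain: Optional[StrainResponseTable] = None,
    geom: Optional[PondGeometry] = None,
) -> Scenario:
    """Generate weather, pond truth, observations and forecast streams.

    Everything derives from one master seed via named sub-streams, so the
    full scenario is bit-reproducible.
    """
    cfg = cfg if cfg is not None else ScenarioConfig()
    master = int(seed if seed is not None else cfg.seed)
    ss = np.random.SeedSequence(master)
    weather_ss, obs_ss, forecast_ss = ss.spawn(3)
    strain = strain if strain is not None else default_strain_table()
    geom = geom if geom is not None else PondGeometry()

    weather = generate_weather(cfg, np.random.default_rng(weather_ss))
    truth_temperature, truth_biomass, observations = generate_truth_and_observations(
        cfg, weather, strain, geom, np.random.default_rng(obs_ss)
    )
    temp_obs = observations[observations["variable"] == "water_temperature"]
    model_forcing = pd.DataFrame(
        {
            "par": weather["par"],
            "water_temperature": temp_obs.set_index("timestamp")["value"],
        }
    )
    return Scenario(
        config=cfg,
        geometry=geom,
        model_thermal=ThermalParams(),
        truth_thermal=ThermalParams(flux_offset=cfg.thermal_flux_offset),
        forecaster_table=strain,
        truth_table=strain.scaled(cfg.growth_scale),
        weather=weather,
        truth_temperature=truth_temperature,
        truth_biomass=truth_biomass,
        observations=observations,
        model_forcing=model_forcing,
        _forecast_entropy=int(forecast_ss.generate_state(1)[0] % (2**31)),
    )
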