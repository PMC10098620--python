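# pondcast

Short-term (7-day) biomass forecasting for outdoor microalgae pond
cultures, with ensemble data assimilation of biomass and water-temperature
measurements.

Outdoor raceway ponds growing strains such as *Chlorella sorokiniana* are
operated on harvesting and dilution decisions made days ahead. Forecasting
the culture requires (i) a growth model driven by light and temperature,
(ii) a pond temperature model driven by weather, (iii) an ensemble weather
forecast, and (iv) a way to condition the model state on the sparse
measurements an operator actually has: optical density (OD750) once or
twice a day and hourly water temperature. `pondcast` implements that full
chain and the twin-experiment machinery to evaluate it.

## Models and method

**Growth model.** The pond is discretized into L equal layers (default 50
over 0.30 m). Surface PAR attenuates with depth following Beer–Lambert
with a scatter-corrected attenuation coefficient

    k_sca = k_a · K_B/(K_B + B) · K_z/(K_z + z),

each layer grows exponentially over a time step at its local specific
rate μ(T, I_j) (a strain-specific measured surface, interpolated
bilinearly), and the pond re-homogenizes after every step. At night the
culture loses biomass by dark respiration at μ_dark(T, I_avg), where
I_avg is the previous day's mean layer light.

**Thermal model.** A mechanically mixed pond is one control volume:
dT/dt = H_net/(ρ c_v d), with H_net = H_s + H_a − (H_b + H_e + H_c)
(net shortwave, net atmospheric longwave, back radiation, latent,
sensible), using Brunt emissivity, Magnus vapour pressure, a quadratic
wind function and a Bowen-ratio sensible flux.

**Data assimilation.** During a spin-up period, N = 200 particles run the
models under cross-correlated forcing perturbations (25% multiplicative
PAR, 2 °C water temperature, correlation 0.48; 4 °C air/dewpoint, 50%
shortwave/wind/pressure, correlations 0.53 and 0.44) plus model-structure
noise (15% of the biomass state per cycle; 1 °C AR(1) for temperature).
Water temperature is assimilated hourly with a standard
sequential-importance-resampling particle filter (PF). Biomass is
assimilated with a particle filter with bias estimation (PFBE): every
particle carries a time-varying model-bias value b_i, propagated between
observations by an adaptive linear model b⁻ = β b⁺ + ε with
β the ratio of successive ensemble-mean deviations from the observation
and ε a small jitter (s = 0.005); the likelihood is evaluated at the
bias-corrected prediction h(x_i − b_i), and x − b is the unbiased state
estimate. The bias never feeds back into model propagation.

**Forecasts.** At each initialization, one trajectory per ensemble-weather
member (default 11) is produced for 7 days: the thermal model forecasts
temperature, then the growth model forecasts biomass from (member PAR,
member temperature). Four experiment designs of increasing sophistication
are built in: open loop (Exp1), direct insertion of the latest observation
(Exp2), biomass PFBE with posterior-mean initialization and constant bias
correction (Exp3), and Exp3 plus temperature PF initialization (Exp4).
Skill is scored by ensemble-mean RMSE and the mean continuous ranked
probability score (MCRPS), computed with the exact pairwise empirical-CDF
estimator.

Because no real pond/weather data ship with the package, a synthetic twin
generator produces everything: diurnal weather, a truth pond run with a
*perturbed* model (growth surfaces scaled by 0.8 and an extra −40 W m⁻²
surface flux, so the forecaster's model systematically overestimates both
biomass and temperature), noisy observations, and biased, lead-dispersing
ensemble weather forecasts.

## Worked example

```python
from pondcast import generate_scenario
from pondcast.engine import run_experiment_suite

scenario = generate_scenario(seed=1)          # 14-day biased twin
results = run_experiment_suite(scenario, seed=7)
for i in (1, 2, 3, 4):
    s = results[i].skill
    print(f"Exp{i}: mean RMSE {s.mean_rmse:.3f} OD750, "
          f"mean MCRPS {s.mean_mcrps:.3f} OD750 ({len(s.cycle_rmse)} cycles)")
```

prints

```
Exp1: mean RMSE 0.811 OD750, mean MCRPS 0.698 OD750 (6 cycles)
Exp2: mean RMSE 0.396 OD750, mean MCRPS 0.284 OD750 (6 cycles)
Exp3: mean RMSE 0.341 OD750, mean MCRPS 0.231 OD750 (6 cycles)
Exp4: mean RMSE 0.330 OD750, mean MCRPS 0.222 OD750 (6 cycles)
```

Reading: open-loop forecasts (Exp1) inherit the model's systematic
overestimation and miss by ~0.8 OD750 on average over six 7-day forecast
cycles. Re-initializing from observations (Exp2) halves the error;
assimilating with bias estimation (Exp3) and adding temperature
assimilation (Exp4) reduce it further — here a 59% improvement of the
full system over open loop.

The same pipeline is scriptable from the shell:

```bash
pondcast synth      --config run.yaml --out-dir out   # write the twin scenario
pondcast assimilate --config run.yaml --out-dir out   # DA spin-up + posteriors
pondcast experiment --config run.yaml --out-dir out --id 4
pondcast evaluate   out/forecasts_exp4.csv out/observations.csv
```

Every run writes a `manifest.json` (seed, config hash, versions) for
exact reproduction.

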