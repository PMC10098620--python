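# Methods

This note records the models, the error parameterization, the numerical
choices, and the open design decisions behind `pondcast`, in the spirit of
a model-description appendix.

## Growth model

Biomass concentration B (carried natively in OD750-equivalent units; a
linear calibration factor converts to g AFDW m⁻³ if configured) evolves in
a pond of depth d = 0.30 m discretized into L = 50 equal layers with
midpoints z_j = (j − ½)·d/L. Per hourly step of constant forcing:

* **Light.** Surface PAR I₀ attenuates to
  I_j = I₀·exp(−k_sca(B, z_j)·B·z_j) with the scatter-corrected
  coefficient k_sca = k_a·K_B/(K_B+B)·K_z/(K_z+z). k_sca ∈ (0, k_a],
  equal to k_a only at B = z = 0.
* **Day** (I₀ > 1 μmol m⁻² s⁻¹; lower light is photosynthetically
  negligible, so this threshold defines the day/night switch): each layer
  grows by exp(μ(T, I_j)·Δt) and the pond instantly re-homogenizes,
  B′ = B·(1/L)·Σ_j exp(μ_j Δt). Mechanically mixed raceways justify
  per-step homogenization; whether the original formulation homogenizes
  per step or per day is not determinable from its description, and the
  per-step choice is the stricter reading of "well mixed".
* **Night**: B′ = B·exp(μ_dark(T, I_avg)·Δt), with I_avg the mean over
  layers and daytime steps of the preceding day's light profile (mean, not
  depth integral — the two differ only by the constant d). I_avg rolls at
  each day→night transition; before any daytime data the I = 0 column of
  the dark-loss surface applies.

Rates are specific rates in day⁻¹; Δt is converted from hours once inside
the step. Exponential updates keep B > 0 whenever B₀ > 0.

μ(T, I) and μ_dark(T, I_avg) are strain-specific measured surfaces,
queried by bilinear interpolation with edge clamping (exact at measured
nodes, bounded by the enclosing cell's corners, defined everywhere). The
shipped default table is **synthetic**: a light-saturating
(half-saturation 100 μmol m⁻² s⁻¹), temperature-optimal (30 °C) response
peaking at 2.2 day⁻¹, with mild temperature/light-dependent dark loss
(−0.02 to −0.08 day⁻¹) and optics k_a = 40 (OD·m)⁻¹, K_B = 2 OD,
K_z = 0.3 m — numbers chosen to make an OD ~ 1 culture optically deep at
30 cm, as dense raceway cultures are. It stands in for proprietary
laboratory parameterizations and is a configuration input like any other.

Layer-midpoint evaluation is second-order accurate for layer means;
doubling L from 50 to 100 changes a daytime step by < 0.5% (asserted in
the tests).

## Thermal model

The pond is treated as a single well-mixed control volume — advective and
diffusive transport vanish, leaving storage against the net surface flux:

    dT/dt = (H_net + F_extra) / (ρ c_v d),   ρ = 1000 kg m⁻³, c_v = 4186 J kg⁻¹ K⁻¹.

H_net = H_s + H_a − (H_b + H_e + H_c) with classical shallow-water-body
component formulas, every constant configurable:

| component | formula | defaults |
|---|---|---|
| net shortwave | (1 − r_s)·SW | r_s = 0.06 |
| net atm. longwave | (1 − r_l)·(a + b√e_a)·σ·T_a⁴ | r_l = 0.03, a = 0.60, b = 0.031 (Brunt, e in hPa) |
| back radiation | ε_w·σ·T_w⁴ | ε_w = 0.97 |
| latent | (c₀ + c₁W²)·(e_s(T_w) − e_a) | c₀ = 9.2, c₁ = 0.46 |
| sensible | γ·(p/1000)·(c₀ + c₁W²)·(T_w − T_a) | γ = 0.61 |

Vapour pressures use the Magnus formula. The latent flux may be negative
(condensation) and is not clipped. `F_extra` (default 0) injects a
constant structural flux error; the twin generator uses it for the truth
pond. Bed/sediment conduction is not modelled (its parameters are
site-specific and unavailable); the twin's negative truth offset plays
that role.

Hourly forcing is integrated with 6 explicit sub-steps per hour; at 30 cm
depth the surface-flux relaxation time is ~10 h, so 10-minute sub-steps
are comfortably stable, and refining to 60 sub-steps changes a 3-day
diurnal trajectory by < 0.05 °C (asserted). Temperatures outside
(−5, 60) °C abort with the offending timestamp.

## Error models and ensembles

Forcing perturbations are standardized cross-correlated fields evolved as
AR(1) processes with a 24 h decorrelation time (white noise would destroy
diurnal coherence; constants would under-disperse), applied as:

* biomass DA: PAR ×(1 + 0.25ζ), water temperature +2 °C·ζ, correlation 0.48;
* thermal DA: air/dewpoint +4 °C·ζ; shortwave/wind/pressure ×(1 + 0.5ζ),
  correlations 0.53 (air–dewpoint) and 0.44 (air–shortwave).

Multiplicative factors are floored at 0.01 so a 50% SD cannot flip signs;
at 25% the floor shifts the mean by < 0.1%. Model-structure error: the
biomass state gets ×(1 + 0.15ζ) at each assimilation cycle; the thermal
ensemble accumulates the increments of a stationary 1 °C AR(1) process
hourly. Ensemble size is N = 200. Observation-error variances (nowhere
standardized for this kind of system) default to R = (0.05·y)² for OD750
and (0.2 °C)² for water temperature, matching the twin generator's
observation noise so the default likelihood is well specified;
misspecification can be explored by varying either side independently.

## Filters

The PF is sequential importance resampling with a Gaussian likelihood and
**systematic resampling** (lowest-variance standard scheme; offspring
counts provably within ⌊Nwᵢ⌋..⌈Nwᵢ⌉). Weights renormalize after every
update; if all likelihoods underflow the weights reset to uniform with a
logged warning rather than aborting an operational run.

The PFBE augments each particle with a bias b_i (sign convention
b = model − truth, so x − b is the unbiased estimate — chosen so a model
that systematically overestimates carries positive bias). Between
observations, b⁻ = β·b⁺ + ε with

* β = (x̄_now − h⁻¹(y_now))/(x̄_prev − h⁻¹(y_prev)) using **prior**
  (pre-update) ensemble means — posterior means hug the observations and
  would destroy the signal; β falls back to 1 (persistence) when the
  previous deviation is < 10⁻⁸ in model units or the ratio leaves
  [0.2, 5], which guards against sign flips and explosions from near-zero
  denominators;
* ε ~ N(0, s·Var(b⁻ at the previous cycle)), s = 0.005, with a floor of
  s·(0.01·|x̄|)² when that variance is degenerate;
* a persistence forward model (β ≡ 1) is available for frequent (hourly)
  observations.

The likelihood uses the bias-corrected prediction h(x_i − b_i); states and
biases resample jointly. **Initial bias ensemble**: N(0, (0.25·|x₀|)²).
A zero-spread start is unrecoverable — the jitter is proportional to the
bias ensemble's own variance, so a collapsed ensemble stays collapsed —
and the prior spread encodes how large a systematic error the filter is
expected to absorb; for outdoor pond growth models that is of order a
quarter of the state. This value was revisited during development after
the bias posterior was observed to under-respond with a smaller prior.

Identifiability caveat: in the biomass twin the growth dynamics are
multiplicative in the state, so the state ensemble itself absorbs much of
each correction and the bias estimate carries mainly the inter-observation
drift. Bias recovery to a known value is therefore demonstrated on a
forcing-dominated twin (constant injected bias, weakly state-dependent
forecast), where the method is identifiable; on the pond twin the test of
the bias machinery is the end-to-end forecast skill ordering.

## Forecast experiments

Spin-up runs over the whole scenario once; forecasts initialize at the
last biomass observation of each day (skipping day 0), six cycles by
default, and are verified only at biomass observation times inside the
(init, init + 7 d] window — matching how sparse OD750 sampling is actually
scored. Initial conditions:

* Exp1 (OL): open-loop model states; no observations.
* Exp2 (DI): the latest OD750 observation, inserted directly.
* Exp3: biomass PFBE — the initialization is the **corrected** posterior
  mean (mean of x − b, the unbiased estimate), and the posterior-mean bias
  is subtracted from every forecast output, floored at 0. Holding the
  init-date bias constant over the horizon is the default; a propagated
  mode (rescaling by β per inter-observation interval) exists but is off.
  Initializing from the bias-blind mean instead is structurally wrong
  under exponential growth — the un-removed bias compounds — and measurably
  degrades skill below direct insertion.
* Exp4: Exp3 plus temperature PF posterior mean as the thermal initial
  condition.

A DA-sample mode (one posterior draw per weather member) is retained as an
alternative to the mean. Forecasts carry no structure noise: spread comes
from the 11 weather members (paired k↔k with biomass trajectories) and,
in sample mode, the initial conditions. The forecast inherits its
previous-day mean light from the spin-up bookkeeping so the first night's
dark loss is consistent.

## Synthetic twin scenarios

The generator emulates a mid-summer Central-Valley-like site: a clear-sky
half-sine shortwave (950 W m⁻² noon peak, 10% day-to-day variability,
PAR = 2.1·SW), sinusoidal air temperature (26 ± 8 °C, maximum 2 h after
solar noon), dewpoint capped below air temperature, diurnal wind and
smooth AR(1) weather noise. The truth pond runs a growth table scaled by
0.8 and an extra −40 W m⁻² surface flux, so the forecaster's nominal
model systematically overestimates biomass and (daytime) temperature —
the configuration the bias-aware filter is designed for. Observations are
hourly temperature (SD 0.2 °C) and daily OD750 at 16:00 (5% SD); the
default run lasts 14 days from OD750 ≈ 0.1. Ensemble weather forecasts
are truth + systematic offsets (−2 °C air, +0.5 m s⁻¹ wind) + AR(1)
errors whose SD grows 30% per day of lead time, 11 members with member 0
as an error-free (offset-only) control.

What the twin does **not** contain — and what passing tests therefore do
not show about real ponds: nutrient limitation, pH/CO₂ dynamics,
contamination and culture crashes, photoacclimation, cloud systems and
weather fronts, spatial temperature gradients, sensor drift or data gaps.
The twin's model error is recoverable by construction; real model error
need not be.

## Verification metrics

RMSE of the ensemble mean, and MCRPS with the exact empirical-CDF
pairwise estimator CRPS = (1/m)Σ|xᵢ−y| − (1/2m²)ΣΣ|xᵢ−xⱼ| (computed in
O(m log m) via the sorted identity; one member reduces to absolute
error). The "fair" (m(m−1)) variant is available but the plain estimator
is the default, being the literal integral of the empirical CDF against
the observation step function (H with ≥). Scores average per cycle over
verifying times, then across cycles.

## Problem sizes in the checks

The shipped verification (test suite and `scripts/acceptance.py`) uses:
a 50-step linear-Gaussian twin with N = 2000 particles against the exact
Kalman recursion; a 40-step logistic-growth twin (r = 0.3, K = 10,
N = 5000) against a 1600-point dense-grid Bayes filter; a 10-cycle
constant-bias twin (N = 200, s = 0.005); and 10 random 14-day pond twins
for the spin-up and experiment-ordering medians. These sizes keep the
full verification under a minute while leaving Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

* Timestamps are timezone-naive local standard time.
* The config schema rejects unknown keys but does not yet cross-validate
  section interactions (e.g. observation hours outside the scenario span
  surface as runtime errors, not config errors).
* The PFBE bias scale is only weakly identified when the state dynamics
  are strongly multiplicative and observations are sparse (see above).
* The well-mixed thermal reduction cannot represent the daytime thermal
  stratification shallow ponds occasionally develop under low wind.
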