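"""Sequential Monte Carlo kernels: SIR particle filter and the particle
filter with bias estimation (PFBE).

The posterior over the model state is represented by N weighted particles.
At each observation, weights are multiplied by a Gaussian likelihood and
the set is systematically resampled back to uniform weights.

The PFBE augments every particle with a time-varying model-bias value
``b_i`` (sign convention b = model - truth, so ``x_i - b_i`` is the
bias-corrected state).  Between observations the bias is propagated by an
adaptive linear model b- = beta * b+ + jitter, where beta is the ratio of
the current to the previous ensemble-mean deviation from the observation;
a small jitter proportional to the prior bias spread keeps the bias
ensemble diverse after resampling.  The bias never feeds back into model
propagation - it only corrects the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

__all__ = [
    "ParticleSet",
    "gaussian_likelihood",
    "update_weights",
    "systematic_resample_indices",
    "resample",
    "compute_beta",
    "propagate_bias",
    "pf_assimilate",
    "pfbe_assimilate",
    "posterior_summary",
]

logger = logging.getLogger(__name__)

#: Clamp for the adaptive bias-propagation slope beta.
BETA_BOUNDS = (0.2, 5.0)
#: |previous deviation| below this falls back to beta = 1 (persistence).
BETA_DENOM_TOL = 1e-8


@dataclass
class ParticleSet:
    """Weighted particle ensemble, optionally bias-augmented.

    ``beta``, ``last_obs_in_model_units``, ``last_prior_mean`` and
    ``prior_bias_var`` carry the PFBE recursion state between successive
    assimilation cycles.
    """

    states: np.ndarray
    weights: np.ndarray
    biases: Optional[np.ndarray] = None
    beta: float = 1.0
    last_update_time: object = None
    last_obs_in_model_units: Optional[float] = None
    last_prior_mean: Optional[float] = None
    prior_bias_var: Optional[float] = None
    #: indices chosen by the most recent resampling step, so callers can
    #: reindex auxiliary per-particle arrays (forcing-error states, etc.)
    last_resample_indices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.states.shape != self.weights.shape or self.states.ndim != 1:
            raise ValueError("states and weights must be matching 1-D arrays")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")
        total = self.weights.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("weights must sum to a positive finite value")
        if abs(total - 1.0) > 1e-9:
            self.weights = self.weights / total
        if self.biases is not None:
            self.biases = np.asarray(self.biases, dtype=float)
            if self.biases.shape != self.states.shape:
                raise ValueError("biases must match states in shape")

    @property
    def n(self) -> int:
        return self.states.size

    def mean(self) -> float:
        return float(np.sum(self.weights * self.states))

    def corrected_states(self) -> np.ndarray:
        """Bias-corrected states x - b (x itself when no biases)."""
        if self.biases is None:
            return self.states
        return self.states - self.biases

    def corrected_mean(self) -> float:
        return float(np.sum(self.weights * self.corrected_states()))

    def ess(self) -> float:
        return float(1.0 / np.sum(self.weights**2))


def gaussian_likelihood(y, hx, R):
    """Gaussian observation density (2 pi R)^(-1/2) exp(-(y-hx)^2 / 2R)."""
    if not R > 0:
        raise ValueError("observation-error variance R must be > 0")
    hx = np.asarray(hx, dtype=float)
    out = np.exp(-((y - hx) ** 2) / (2.0 * R)) / np.sqrt(2.0 * np.pi * R)
    return float(out) if out.ndim == 0 else out


def update_weights(
    ps: ParticleSet,
    y: float,
    R: float,
    *,
    bias_aware: bool = False,
    obs_factor: float = 1.0,
) -> ParticleSet:
    """Multiply prior weights by the observation likelihood and normalize.

    ``bias_aware`` evaluates the likelihood at the bias-corrected predicted
    observation h(x_i - b_i); ``obs_factor`` is the linear observation
    operator h (model units -> observation units).  If every likelihood
    underflows to zero the weights are reset uniform with a warning.
    """
    hx = obs_factor * (ps.corrected_states() if bias_aware else ps.states)
    like = gaussian_likelihood(y, hx, R)
    w = ps.weights * like
    total = w.sum()
    if not np.isfinite(total) or total <= 0.0:
        logger.warning(
            "particle degeneracy: all likelihoods underflowed, resetting "
            "weights uniform"
        )
        w = np.full(ps.n, 1.0 / ps.n)
    else:
        w = w / total
    return replace(ps, weights=w)


def systematic_resample_indices(
    weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Systematic resampling: one uniform offset, N evenly spaced strata.

    Offspring counts satisfy floor(N w_i) <= count_i <= ceil(N w_i).
    """
    weights = np.asarray(weights, dtype=float)
    n = weights.size
    total = weights.sum()
    if not total > 0:
        raise ValueError("cannot resample an all-zero weight vector")
    positions = (rng.random() + np.arange(n)) / n
    cumulative = np.cumsum(weights / total)
    cumulative[-1] = 1.0  # guard against rounding
    return np.searchsorted(cumulative, positions)


def resample(ps: ParticleSet, rng: np.random.Generator) -> ParticleSet:
    """Systematic resampling; biases follow their states; weights -> 1/N."""
    idx = systematic_resample_indices(ps.weights, rng)
    return replace(
        ps,
        states=ps.states[idx],
        weights=np.full(ps.n, 1.0 / ps.n),
        biases=None if ps.biases is None else ps.biases[idx],
        last_resample_indices=idx,
    )


def compute_beta(
    mean_now: float,
    mean_prev: float,
    obs_now: float,
    obs_prev: float,
    *,
    tol: float = BETA_DENOM_TOL,
    bounds=BETA_BOUNDS,
) -> float:
    """Adaptive bias-propagation slope.

    beta = (mean_now - obs_now) / (mean_prev - obs_prev) with observations
    already mapped into model units.  Falls back to 1 (persistence) when
    the previous deviation is degenerate or the ratio leaves ``bounds``.
    """
    denom = mean_prev - obs_prev
    if abs(denom) < tol:
        return 1.0
    beta = (mean_now - obs_now) / denom
    if not np.isfinite(beta) or not (bounds[0] <= beta <= bounds[1]):
        return 1.0
    return float(beta)


def propagate_bias(
    biases: np.ndarray,
    beta: float,
    s: float,
    rng: np.random.Generator,
    *,
    prior_bias_var: Optional[float] = None,
    mean_state: float = 0.0,
) -> np.ndarray:
    """Prior biases at the observation time: b- = beta * b+ + eps.

    eps ~ N(0, s * Var(prior biases at the previous cycle)); when that
    variance is unavailable or zero, the jitter variance is floored at
    s * (0.01 * |mean_state|)^2 so a collapsed bias ensemble can still
    regain diversity.
    """
    biases = np.asarray(biases, dtype=float)
    var = prior_bias_var if prior_bias_var is not None else 0.0
    if not var > 0:
        var = (0.01 * abs(mean_state)) ** 2
    sd = np.sqrt(s * var)
    return beta * biases + sd * rng.standard_normal(biases.shape)


def pf_assimilate(
    ps: ParticleSet,
    y: float,
    R: float,
    rng: np.random.Generator,
    *,
    obs_factor: float = 1.0,
    time=None,
) -> ParticleSet:
    """Standard SIR update: weight by the likelihood, then resample."""
    out = update_weights(ps, y, R, bias_aware=False, obs_factor=obs_factor)
    out = resample(out, rng)
    out.last_update_time = time
    out.last_obs_in_model_units = y / obs_factor
    return out


def pfbe_assimilate(
    ps: ParticleSet,
    y: float,
    R: float,
    rng: np.random.Generator,
    *,
    s: float = 0.005,
    obs_factor: float = 1.0,
    bias_model: str = "adaptive",
    time=None,
) -> ParticleSet:
    """Bias-aware update: propagate biases, weight on h(x - b), resample.

    ``bias_model`` selects the adaptive linear forward model (default,
    suited to sparse observations) or persistence (beta = 1, suited to
    frequent observations).  The first cycle uses beta = 1 because no
    previous deviation exists.
    """
    if ps.biases is None:
        raise ValueError("pfbe_assimilate requires a bias-augmented ParticleSet")
    if bias_model not in ("adaptive", "persistence"):
        raise ValueError(f"unknown bias_model {bias_model!r}")
    y_model = y / obs_factor
    prior_mean = ps.mean()
    if (
        bias_model == "adaptive"
        and ps.last_obs_in_model_units is not None
        and ps.last_prior_mean is not None
    ):
        beta = compute_beta(
            prior_mean, ps.last_prior_mean, y_model, ps.last_obs_in_model_units
        )
    else:
        beta = 1.0
    b_prior = propagate_bias(
        ps.biases,
        beta,
        s,
        rng,
        prior_bias_var=ps.prior_bias_var,
        mean_state=prior_mean,
    )
    ps = replace(ps, biases=b_prior)
    # Spread of this cycle's prior biases feeds the next cycle's jitter.
    prior_bias_var = float(np.var(b_prior))
    out = update_weights(ps, y, R, bias_aware=True, obs_factor=obs_factor)
    out = resample(out, rng)
    out.beta = beta
    out.last_update_time = time
    out.last_obs_in_model_units = y_model
    out.last_prior_mean = prior_mean
    out.prior_bias_var = prior_bias_var
    return out


def _weighted_quantiles(
    values: np.ndarray, weights: np.ndarray, qs: np.ndarray
) -> np.ndarray:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return np.interp(qs, cum, v)


def posterior_summary(ps: ParticleSet) -> Dict[str, object]:
    """Weighted mean, SD, standard quantiles and effective sample size."""
    mean = ps.mean()
    var = float(np.sum(ps.weights * (ps.states - mean) ** 2))
    qs = np.array([0.05, 0.25, 0.50, 0.75, 0.95])
    quantiles = _weighted_quantiles(ps.states, ps.weights, qs)
    return {
        "mean": mean,
        "sd": float(np.sqrt(var)),
        "quantiles": {int(100 * q): float(v) for q, v in zip(qs, quantiles)},
        "ess": ps.ess(),
    }
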