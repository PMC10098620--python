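"""Particle filter kernels against closed-form and brute-force oracles."""

import numpy as np
import pytest

from pondcast import (
    ParticleSet,
    compute_beta,
    gaussian_likelihood,
    pf_assimilate,
    pfbe_assimilate,
    posterior_summary,
    propagate_bias,
    resample,
    update_weights,
)
from pondcast.filters import systematic_resample_indices


def uniform_set(states, biases=None) -> ParticleSet:
    states = np.asarray(states, dtype=float)
    return ParticleSet(
        states=states,
        weights=np.full(states.size, 1.0 / states.size),
        biases=biases,
    )


class TestGaussianLikelihood:
    def test_peak_value_unit_variance(self):
        assert gaussian_likelihood(1.0, 1.0, 1.0) == pytest.approx(
            1.0 / np.sqrt(2 * np.pi)
        )

    def test_symmetric_pair(self):
        assert gaussian_likelihood(1.0, 1.3, 0.1) == pytest.approx(
            gaussian_likelihood(1.0, 0.7, 0.1)
        )

    def test_hand_evaluated_density(self):
        expected = np.exp(-0.04 / 0.02) / np.sqrt(2 * np.pi * 0.01)
        assert gaussian_likelihood(1.0, 0.8, 0.01) == pytest.approx(expected)

    def test_rejects_non_positive_variance(self):
        with pytest.raises(ValueError):
            gaussian_likelihood(1.0, 1.0, 0.0)


class TestUpdateWeights:
    def test_equal_likelihoods_keep_uniform(self):
        ps = update_weights(uniform_set([1.0, 1.0, 1.0]), 1.0, 0.5)
        assert np.allclose(ps.weights, 1 / 3)

    def test_hand_normalization(self):
        # prior (0.5, 0.5), likelihood ratio 3:1 -> posterior (0.75, 0.25)
        ps = ParticleSet(states=[0.0, 2.0], weights=[0.5, 0.5])
        R = 1.0
        y = 0.0
        out = update_weights(ps, y, R)
        like = gaussian_likelihood(y, np.array([0.0, 2.0]), R)
        expected = like / like.sum()
        assert np.allclose(out.weights, expected)
        # and the same pattern with explicit likelihood values 0.3 / 0.1
        manual = np.array([0.5 * 0.3, 0.5 * 0.1])
        assert np.allclose(manual / manual.sum(), [0.75, 0.25])

    def test_underflow_resets_uniform(self, caplog):
        ps = uniform_set([1e6, 2e6])
        out = update_weights(ps, 0.0, 1e-6)
        assert np.allclose(out.weights, 0.5)

    def test_linear_gaussian_posterior_mean_matches_kalman(self, rng):
        """Prior N(0,1), obs y=1 with R=1: exact posterior mean is 0.5."""
        states = rng.standard_normal(100_000)
        ps = update_weights(uniform_set(states), 1.0, 1.0)
        assert ps.mean() == pytest.approx(0.5, abs=0.02)


class TestResample:
    def test_degenerate_weights_give_all_copies(self, rng):
        ps = ParticleSet(states=[1.0, 2.0, 3.0, 4.0], weights=[1.0, 0, 0, 0])
        out = resample(ps, rng)
        assert np.all(out.states == 1.0)
        assert np.allclose(out.weights, 0.25)

    def test_offspring_counts_within_floor_ceiling(self):
        weights = np.array([0.5, 0.25, 0.125, 0.125])
        n = weights.size
        for offset_seed in range(200):
            idx = systematic_resample_indices(
                weights, np.random.default_rng(offset_seed)
            )
            counts = np.bincount(idx, minlength=n)
            assert np.all(counts >= np.floor(n * weights))
            assert np.all(counts <= np.ceil(n * weights))

    def test_unbiased_in_expectation(self):
        weights = np.array([0.4, 0.3, 0.2, 0.1])
        states = np.array([1.0, 2.0, 3.0, 4.0])
        total = np.zeros(4)
        trials = 10_000
        for t in range(trials):
            idx = systematic_resample_indices(weights, np.random.default_rng(t))
            total += np.bincount(idx, minlength=4)
        assert np.allclose(total / trials, 4 * weights, atol=0.02)

    def test_biases_follow_states(self, rng):
        ps = ParticleSet(
            states=[1.0, 2.0], weights=[0.0, 1.0], biases=[0.1, 0.2]
        )
        out = resample(ps, rng)
        assert np.all(out.states == 2.0) and np.all(out.biases == 0.2)


class TestComputeBeta:
    def test_equal_deviations(self):
        assert compute_beta(1.2, 1.1, 1.0, 0.9) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert compute_beta(1.4, 1.2, 1.0, 1.0) == pytest.approx(2.0)

    def test_degenerate_denominator_falls_back(self):
        assert compute_beta(1.4, 1.0, 1.0, 1.0) == 1.0

    def test_out_of_bounds_falls_back(self):
        assert compute_beta(10.0, 1.001, 0.0, 1.0) == 1.0


class TestPropagateBias:
    def test_identity_when_beta_one_no_jitter(self, rng):
        b = np.array([0.1, 0.2])
        out = propagate_bias(b, 1.0, 0.005, rng, prior_bias_var=0.0,
                             mean_state=0.0)
        assert np.allclose(out, b)

    def test_linear_map(self, rng):
        out = propagate_bias(np.array([0.1, 0.2]), 2.0, 0.005, rng,
                             prior_bias_var=0.0, mean_state=0.0)
        assert np.allclose(out, [0.2, 0.4])

    def test_jitter_magnitude_monte_carlo(self, rng):
        out = propagate_bias(np.zeros(10_000), 1.0, 0.005, rng,
                             prior_bias_var=0.04)
        assert out.std() == pytest.approx(np.sqrt(0.005 * 0.04), rel=0.03)


class TestPfAssimilate:
    def test_observation_at_ensemble_mean_keeps_mean(self, rng):
        states = np.concatenate([np.linspace(-1, 1, 2000)]) + 5.0
        ps = uniform_set(states)
        out = pf_assimilate(ps, 5.0, 0.25, rng)
        assert out.mean() == pytest.approx(5.0, abs=0.05)

    def test_tiny_R_collapses_to_observation(self, rng):
        ps = uniform_set(np.linspace(0, 10, 500))
        for _ in range(5):
            ps = pf_assimilate(ps, 4.0, 1e-4, rng)
        assert ps.mean() == pytest.approx(4.0, abs=0.05)

    def test_tracks_exact_kalman_filter(self):
        """50-step linear-Gaussian twin: PF vs closed-form Kalman."""
        a, Q, R, N, steps = 0.9, 0.5**2, 0.5**2, 2000, 50
        rng = np.random.default_rng(7)
        x_true = 0.0
        particles = rng.standard_normal(N)
        ps = ParticleSet(states=particles, weights=np.full(N, 1 / N))
        mu_kf, var_kf = 0.0, 1.0
        mean_err, var_err, scale = [], [], []
        for _ in range(steps):
            x_true = a * x_true + np.sqrt(Q) * rng.standard_normal()
            y = x_true + np.sqrt(R) * rng.standard_normal()
            # PF: propagate + assimilate
            ps.states = a * ps.states + np.sqrt(Q) * rng.standard_normal(N)
            ps = pf_assimilate(ps, y, R, rng)
            # exact Kalman recursion
            mu_p, var_p = a * mu_kf, a**2 * var_kf + Q
            k = var_p / (var_p + R)
            mu_kf, var_kf = mu_p + k * (y - mu_p), (1 - k) * var_p
            mean_err.append(abs(ps.mean() - mu_kf))
            var_err.append(abs(np.var(ps.states) - var_kf) / var_kf)
            scale.append(abs(mu_kf))
        assert np.mean(mean_err) / max(np.mean(scale), np.sqrt(var_kf)) < 0.05
        assert np.mean(var_err) < 0.05


class TestPfbeAssimilate:
    def _constant_bias_twin(self, seed, n=200, cycles=10, bias=0.3):
        rng = np.random.default_rng(seed)
        truth = 1.0
        ps = ParticleSet(
            states=np.full(n, truth + bias),
            weights=np.full(n, 1 / n),
            biases=rng.normal(0.0, 0.25, n),
        )
        R = 0.05**2
        b_means, corr_err, raw_err = [], [], []
        for _ in range(cycles):
            # forcing-dominated model forecast: re-biased each cycle
            ps.states = truth + bias + 0.1 * rng.standard_normal(n)
            y = truth + np.sqrt(R) * rng.standard_normal()
            ps = pfbe_assimilate(ps, y, R, rng, s=0.005)
            b_means.append(float(np.sum(ps.weights * ps.biases)))
            corr_err.append((ps.corrected_mean() - truth) ** 2)
            raw_err.append((ps.mean() - truth) ** 2)
        return b_means[-1], np.sqrt(np.mean(corr_err)), np.sqrt(np.mean(raw_err))

    def test_unbiased_twin_keeps_bias_near_zero(self):
        vals = [self._constant_bias_twin(s, bias=0.0)[0] for s in range(5)]
        assert abs(np.median(vals)) < 0.1  # within 2 observation SDs

    def test_recovers_constant_bias(self):
        recovered = [self._constant_bias_twin(s)[0] for s in range(10)]
        assert np.median(recovered) == pytest.approx(0.3, abs=0.1)

    def test_corrected_state_beats_uncorrected(self):
        corr, raw = zip(*[self._constant_bias_twin(s)[1:] for s in range(10)])
        assert np.median(corr) < np.median(raw)

    def test_growth_twin_beta_exceeds_one(self):
        """Exponential growth with multiplicative model error: deviations
        grow between cycles, so the adaptive slope should run above 1."""
        rng = np.random.default_rng(3)
        n = 500
        truth = 1.0
        model = 1.0
        ps = ParticleSet(
            states=np.full(n, model),
            weights=np.full(n, 1 / n),
            biases=rng.normal(0, 0.05, n),
        )
        betas = []
        for _ in range(8):
            truth *= 1.3
            model = ps.mean() * 1.3 * 1.15  # 15% multiplicative model error
            ps.states = model * (1 + 0.05 * rng.standard_normal(n))
            y = truth * (1 + 0.01 * rng.standard_normal())
            ps = pfbe_assimilate(ps, y, (0.02 * y) ** 2, rng, s=0.005)
            betas.append(ps.beta)
        assert np.mean(np.array(betas[1:]) > 1.0) > 0.5

    def test_requires_bias_ensemble(self, rng):
        with pytest.raises(ValueError, match="bias-augmented"):
            pfbe_assimilate(uniform_set([1.0, 2.0]), 1.0, 0.1, rng)


class TestPosteriorSummary:
    def test_equal_weights_match_unweighted(self, rng):
        states = rng.standard_normal(5000)
        summ = posterior_summary(uniform_set(states))
        assert summ["mean"] == pytest.approx(states.mean(), abs=1e-9)
        assert summ["sd"] == pytest.approx(states.std(), rel=1e-6)
        assert summ["quantiles"][50] == pytest.approx(
            np.median(states), abs=0.05
        )

    def test_degenerate_weight_ess(self):
        ps = ParticleSet(states=[1.0, 2.0, 3.0], weights=[1.0, 0.0, 0.0])
        summ = posterior_summary(ps)
        assert summ["ess"] == pytest.approx(1.0)

    def test_weighted_quantiles_against_resampling_oracle(self, rng):
        states = rng.standard_normal(300)
        w = rng.random(300)
        ps = ParticleSet(states=states, weights=w)
        summ = posterior_summary(ps)
        draws = rng.choice(states, size=1_000_000, p=ps.weights)
        for q in (25, 50, 75):
            oracle = np.percentile(draws, q)
            spread = states.std()
            assert abs(summ["quantiles"][q] - oracle) < 0.05 * spread

    def test_ess_bounds(self, rng):
        for _ in range(10):
            w = rng.random(50)
            ps = ParticleSet(states=np.zeros(50), weights=w)
            assert 1.0 <= ps.ess() <= 50.0
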