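"""Layered growth model: attenuation, light profiles, day/night updates."""

import numpy as np
import pandas as pd
import pytest

from pondcast import (
    BiomassState,
    PondGeometry,
    bgm_step,
    daily_average_light,
    light_profile,
    scatter_corrected_k,
    simulate_bgm,
)
from pondcast.bgm import day_growth_factor
from pondcast.strain import dark_loss_rate, growth_rate

from conftest import constant_rate_table


class TestScatterCorrectedK:
    def test_limits(self, toy_table):
        assert scatter_corrected_k(toy_table, 0.0, 0.0) == pytest.approx(
            toy_table.k_a
        )
        assert scatter_corrected_k(
            toy_table, toy_table.K_B, toy_table.K_z
        ) == pytest.approx(toy_table.k_a / 4.0)

    def test_hand_evaluated_value(self, toy_table):
        # 0.2 * (1.5/2.0) * (0.1/0.15) = 0.1
        assert scatter_corrected_k(toy_table, 0.5, 0.05) == pytest.approx(0.1)

    def test_bounded_by_k_a(self, toy_table, rng):
        B = rng.uniform(0, 10, 100)
        z = rng.uniform(0, 0.3, 100)
        k = scatter_corrected_k(toy_table, B, z)
        assert np.all(k > 0) and np.all(k <= toy_table.k_a)

    def test_rejects_negative_inputs(self, toy_table):
        with pytest.raises(ValueError):
            scatter_corrected_k(toy_table, -0.1, 0.0)


class TestLightProfile:
    def test_no_biomass_means_no_attenuation(self, toy_table, geometry):
        profile = light_profile(800.0, 0.0, geometry, toy_table)
        assert profile.shape == (geometry.n_layers,)
        assert np.allclose(profile, 800.0)

    def test_dark_surface_stays_dark(self, toy_table, geometry):
        assert np.allclose(light_profile(0.0, 1.0, geometry, toy_table), 0.0)

    def test_monotone_decreasing_with_depth(self, toy_table, geometry):
        profile = light_profile(2000.0, 1.0, geometry, toy_table)
        assert np.all(np.diff(profile) < 0)

    def test_hand_computed_exponential(self, toy_table):
        geom = PondGeometry(depth=0.30, n_layers=1)  # midpoint z = 0.15
        k = 0.2 * (1.5 / 2.5) * (0.1 / 0.25)
        expected = 2000.0 * np.exp(-k * 1.0 * 0.15)
        assert light_profile(2000.0, 1.0, geom, toy_table)[0] == pytest.approx(
            expected
        )


class TestBgmStep:
    def test_zero_rate_leaves_biomass_unchanged(self, geometry):
        table = constant_rate_table(0.0)
        state = BiomassState(B=1.3)
        out = bgm_step(state, 25.0, 800.0, 1.0, table, geometry)
        assert out.B == pytest.approx(1.3)

    def test_single_layer_day_growth_closed_form(self):
        # mu = 1.2 /day for 1 h: factor e^{0.05}
        table = constant_rate_table(1.2)
        geom = PondGeometry(n_layers=1)
        out = bgm_step(BiomassState(B=2.0), 25.0, 800.0, 1.0, table, geom)
        assert out.B == pytest.approx(2.0 * np.exp(0.05))

    def test_night_dark_loss_closed_form(self, geometry):
        # mu_dark = -0.24 /day for 1 h: factor e^{-0.01}
        table = constant_rate_table(0.0, mu_dark=-0.24)
        out = bgm_step(BiomassState(B=2.0), 20.0, 0.0, 1.0, table, geometry)
        assert out.B == pytest.approx(2.0 * np.exp(-0.01))

    def test_positivity_preserved(self, strain_table, geometry, rng):
        state = BiomassState(B=0.5, I_avg_prev_day=200.0)
        for _ in range(50):
            I0 = float(rng.uniform(0, 2000))
            state = bgm_step(state, float(rng.uniform(5, 40)), I0, 1.0,
                             strain_table, geometry)
            assert state.B > 0

    def test_single_layer_matches_pointwise_rate(self, strain_table):
        """With one layer the day update is exactly B * e^{mu(T, I(z1)) dt}."""
        geom = PondGeometry(n_layers=1)
        B, T, I0 = 0.8, 28.0, 1500.0
        I1 = light_profile(I0, B, geom, strain_table)[0]
        mu = growth_rate(strain_table, T, I1)
        out = bgm_step(BiomassState(B=B), T, I0, 1.0, strain_table, geom)
        assert out.B == pytest.approx(B * np.exp(mu / 24.0))


class TestDailyAverageLight:
    def test_constant_profile(self):
        assert daily_average_light([np.full(5, 300.0)] * 4) == pytest.approx(300.0)

    def test_mean_of_two_steps(self):
        profiles = [np.full(3, 100.0), np.full(3, 300.0)]
        assert daily_average_light(profiles) == pytest.approx(200.0)

    def test_flat_average_oracle(self, rng):
        profiles = [rng.uniform(0, 500, 3) for _ in range(2)]
        assert daily_average_light(profiles) == pytest.approx(
            np.concatenate(profiles).mean()
        )

    def test_empty_window_returns_zero(self, caplog):
        assert daily_average_light([]) == 0.0


def _forcing(hours, par, temp):
    index = pd.date_range("2021-06-01", periods=hours, freq="h")
    return pd.DataFrame({"par": par, "water_temperature": temp}, index=index)


class TestSimulateBgm:
    def test_zero_rates_give_flat_trajectory(self, geometry):
        table = constant_rate_table(0.0, 0.0)
        forcing = _forcing(48, np.tile([0.0] * 6 + [800.0] * 12 + [0.0] * 6, 2),
                           np.full(48, 25.0))
        traj = simulate_bgm(forcing, 1.0, table, geometry)
        assert np.allclose(traj.values, 1.0)

    def test_constant_rate_perpetual_day_closed_form(self):
        table = constant_rate_table(1.0)
        geom = PondGeometry(n_layers=1)
        forcing = _forcing(24, np.full(24, 800.0), np.full(24, 25.0))
        traj = simulate_bgm(forcing, 0.5, table, geom)
        assert traj.iloc[-1] == pytest.approx(0.5 * np.e)

    def test_gap_in_forcing_raises_named_error(self, strain_table, geometry):
        forcing = _forcing(10, np.full(10, 500.0), np.full(10, 25.0))
        forcing = forcing.drop(forcing.index[4])
        with pytest.raises(ValueError, match="gap-free hourly"):
            simulate_bgm(forcing, 0.5, strain_table, geometry)

    def test_matches_straight_line_reference_integrator(
        self, strain_table, geometry
    ):
        """Three diurnal days against an independently coded reference."""
        hours = 72
        hour = np.arange(hours) % 24
        par = np.where((hour >= 6) & (hour < 20),
                       1800.0 * np.sin(np.pi * (hour - 6) / 14.0), 0.0)
        temp = 25.0 + 6.0 * np.cos(2 * np.pi * (hour - 15) / 24.0)
        forcing = _forcing(hours, par, temp)
        traj = simulate_bgm(forcing, 0.2, strain_table, geometry)

        # reference: plain loops, no shared code path with the model driver
        z = (np.arange(geometry.n_layers) + 0.5) * (
            geometry.depth / geometry.n_layers
        )
        B = 0.2
        i_avg = 0.0
        day_means = []
        was_day = False
        ref = []
        for t in range(hours):
            if par[t] > 1.0:
                if not was_day:
                    day_means = []
                factors = []
                layer_I = []
                for zj in z:
                    k = (strain_table.k_a
                         * strain_table.K_B / (strain_table.K_B + B)
                         * strain_table.K_z / (strain_table.K_z + zj))
                    Ij = par[t] * np.exp(-k * B * zj)
                    layer_I.append(Ij)
                    factors.append(
                        np.exp(growth_rate(strain_table, temp[t], Ij) / 24.0)
                    )
                B *= float(np.mean(factors))
                day_means.append(float(np.mean(layer_I)))
                was_day = True
            else:
                if was_day and day_means:
                    i_avg = float(np.mean(day_means))
                B *= float(
                    np.exp(dark_loss_rate(strain_table, temp[t], i_avg) / 24.0)
                )
                was_day = False
            ref.append(B)
        assert np.allclose(traj.values, ref, rtol=1e-10)

    def test_layer_refinement_stability(self, strain_table):
        """Doubling the layer count changes the day step by < 0.5%."""
        f50, _ = day_growth_factor(
            1.0, 28.0, 1500.0, 1.0, strain_table, PondGeometry(n_layers=50)
        )
        f100, _ = day_growth_factor(
            1.0, 28.0, 1500.0, 1.0, strain_table, PondGeometry(n_layers=100)
        )
        assert abs(float(f100) / float(f50) - 1.0) < 0.005
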