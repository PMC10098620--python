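import numpy as np
import pandas as pd
import pytest

from pondcast import (
    PondGeometry,
    ScenarioConfig,
    StrainResponseTable,
    default_strain_table,
    generate_scenario,
)


@pytest.fixture(scope="session")
def toy_table() -> StrainResponseTable:
    """Small strain table with hand-checkable bilinear cells.

    The (100, 500) light cell of the growth surface holds the values
    0.5/2.0/1.0/4.0 used in the worked interpolation examples; the dark
    column (I = 0) is present as required.
    """
    return StrainResponseTable(
        temperature_grid=[20.0, 30.0],
        light_grid=[0.0, 100.0, 500.0],
        growth_surface=[[0.0, 0.5, 2.0], [0.0, 1.0, 4.0]],
        dark_loss_surface=[[-0.02, -0.02, -0.04], [-0.06, -0.06, -0.08]],
        k_a=0.2,
        K_B=1.5,
        K_z=0.1,
    )


@pytest.fixture(scope="session")
def strain_table() -> StrainResponseTable:
    return default_strain_table()


@pytest.fixture(scope="session")
def geometry() -> PondGeometry:
    return PondGeometry()


@pytest.fixture(scope="session")
def small_scenario():
    """A short twin scenario for engine tests (fast to spin up)."""
    cfg = ScenarioConfig(duration_days=10, seed=11)
    return generate_scenario(cfg)


def constant_rate_table(mu: float, mu_dark: float = 0.0) -> StrainResponseTable:
    """Strain table whose growth/dark surfaces are constant everywhere."""
    return StrainResponseTable(
        temperature_grid=[0.0, 50.0],
        light_grid=[0.0, 3000.0],
        growth_surface=np.full((2, 2), mu),
        dark_loss_surface=np.full((2, 2), mu_dark),
        k_a=0.2,
        K_B=1.5,
        K_z=0.1,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def diurnal_met() -> pd.DataFrame:
    """Three days of smooth synthetic meteorology for thermal tests."""
    index = pd.date_range("2021-06-01", periods=72, freq="h")
    hour = index.hour.to_numpy().astype(float)
    solar = np.clip(np.sin(np.pi * (hour - 6.0) / 14.0), 0.0, None)
    solar[(hour < 6.0) | (hour > 20.0)] = 0.0
    return pd.DataFrame(
        {
            "air_temperature": 25.0 + 8.0 * np.cos(2 * np.pi * (hour - 15) / 24),
            "dewpoint": np.full(72, 10.0),
            "wind_speed": np.full(72, 2.0),
            "pressure": np.full(72, 1008.0),
            "shortwave": 900.0 * solar,
        },
        index=index,
    )
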