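import numpy as np
import pytest

from heatecon.synthetic import (
    SyntheticClimateConfig,
    ToyEconomyConfig,
    generate_meteo,
    generate_toy_economy,
)


@pytest.fixture(scope="session")
def small_meteo():
    """One year of hourly meteorology on a 2×2 grid (warm climate)."""
    cfg = SyntheticClimateConfig(grid_shape=(2, 2), years=(2001, 2001), base_mean=20.0, seed=3)
    return generate_meteo(cfg)


@pytest.fixture(scope="session")
def toy_economy():
    return generate_toy_economy(ToyEconomyConfig(n_regions=2, n_countries=1, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
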