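import logging

import numpy as np
import pytest

from cropclim.synthetic import SyntheticConfig

# ridge warnings from deliberately degenerate covariances are expected noise
logging.getLogger("cropclim.aggregation").setLevel(logging.ERROR)

ZERO_NOISE = dict(
    temp_day_sd=0.0, temp_year_sd=0.0, precip_day_sd=0.0, precip_year_sd=0.0
)


def zero_warming_kwargs(scenarios=("rcp45-like", "rcp85-like")):
    return dict(scenario_warming={s: 0.0 for s in scenarios}, gcm_spread=0.0)


def make_config(seed=7, **kw):
    """Small, fast default synthetic configuration for unit tests."""
    defaults = dict(
        seed=seed,
        grid_shape=(4, 10),
        n_counties=8,
        n_years_hist=6,
        n_gcms=3,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    return make_config()


@pytest.fixture(scope="session")
def tiny_dataset():
    from cropclim.synthetic import generate_climate

    return generate_climate(make_config())
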