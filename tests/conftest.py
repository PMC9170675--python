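import numpy as np
import pytest

from pyfbst import (
    FLAT_REFERENCE,
    Hypothesis,
    build_surprise,
    estimate_posterior_density,
    gen_normal_draws,
)


@pytest.fixture(scope="session")
def std_normal_draws():
    """20,000 seeded draws from a standard normal posterior."""
    return gen_normal_draws(0.0, 1.0, 20_000, seed=42)


@pytest.fixture(scope="session")
def std_normal_density(std_normal_draws):
    return estimate_posterior_density(std_normal_draws)


@pytest.fixture(scope="session")
def std_normal_surprise(std_normal_density):
    """Flat-reference surprise function of the standard normal posterior."""
    return build_surprise(std_normal_density, FLAT_REFERENCE)


@pytest.fixture()
def point_null():
    return Hypothesis(0.0, dim_theta=1, dim_null=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
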