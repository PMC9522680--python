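import pytest

from evpexposure.io import default_design, default_generation_params, default_registry
from evpexposure.synthetic_study import generate_study


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def sessions(design):
    """One default synthetic crossover dataset (seed 1)."""
    return generate_study(design, default_generation_params(seed=1))


@pytest.fixture(scope="session")
def noise_free_sessions(design):
    """Zero CVs, zero sham background: product values hit the true means."""
    params = default_generation_params(seed=0)
    params.cv_between = 0.0
    params.cv_within = 0.0
    return generate_study(design, params)


@pytest.fixture(scope="session")
def registry():
    return {c.name: c for c in default_registry()}
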