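import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rootstress.synthetic import SyntheticConfig, builtin_table_fixtures, generate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixtures():
    return builtin_table_fixtures()


@pytest.fixture(scope="session")
def trait_dataset():
    """Table-calibrated 4x4 design, trait-level sampling."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def raw_dataset():
    """Table-calibrated 4x4 design generated from raw measurements."""
    return generate_dataset(SyntheticConfig(seed=2, mode="raw_level"))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
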