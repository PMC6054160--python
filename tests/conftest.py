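import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from phenosync import io_cli, synth

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def default_dataset() -> synth.SynthDataset:
    """One default synthetic season shared by read-only tests."""
    return synth.generate_dataset(seed=42)


@pytest.fixture(scope="session")
def default_phenology(default_dataset):
    series = io_cli.read_census_frame(default_dataset.census)
    return io_cli.phenology_table(series)
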