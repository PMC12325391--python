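import pytest
from hypothesis import HealthCheck, settings

from ssdcompliance import default_registry, filter_agricultural, fixture_small

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def fixture_samples():
    return fixture_small()


@pytest.fixture(scope="session")
def agricultural_samples(fixture_samples):
    return filter_agricultural(fixture_samples)


@pytest.fixture(scope="session")
def samples_by_id(fixture_samples):
    return {s.sample_id: s for s in fixture_samples}
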