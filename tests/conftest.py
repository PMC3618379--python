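import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", max_examples=50, derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from nmrval.synthetic_fixtures import generate, preset_spec


@pytest.fixture(scope="session")
def basic_data():
    return generate(preset_spec("basic", seed=11))


@pytest.fixture(scope="session")
def violations_data():
    return generate(preset_spec("violations", seed=7))


@pytest.fixture(scope="session")
def clustered_data():
    return generate(preset_spec("clustered", seed=5))


@pytest.fixture(scope="session")
def rdc_data():
    return generate(preset_spec("rdc", seed=3))


@pytest.fixture(scope="session")
def shifts_data():
    return generate(preset_spec("shifts", seed=13))
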