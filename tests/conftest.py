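import pytest
from hypothesis import HealthCheck, settings

from titrkin import GOX_REFERENCE_PARAMS, ReactorSpec, generate_rate_table, reference_design

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def truth():
    """Reference combined-design parameter triple used as ground truth."""
    return GOX_REFERENCE_PARAMS["titr_combined"]


@pytest.fixture(scope="session")
def spec():
    return ReactorSpec()


@pytest.fixture(scope="session")
def combined_noiseless(truth):
    """Noise-free rate observations on the full two-pressure design."""
    atm, hp = reference_design(noise_cv=0.0)
    return generate_rate_table(atm, truth) + generate_rate_table(hp, truth)
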