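import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trihelix import synthetic_parameter_table, validate_sequence

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_params():
    return synthetic_parameter_table("toy-stabilizing")


@pytest.fixture(scope="session")
def zeros_params():
    return synthetic_parameter_table("zeros")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pog7():
    return validate_sequence("POG" * 7, id="A")
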