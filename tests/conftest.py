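import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ideal_arg():
    from polarframe import build_ideal_residue

    return build_ideal_residue("ARG")


@pytest.fixture
def ideal_lys():
    from polarframe import build_ideal_residue

    return build_ideal_residue("LYS")
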