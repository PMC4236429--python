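import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20140120)


@pytest.fixture
def params():
    """Canonical parameter set: t0 = K N s = 1000, a* = n*/N = 5e-3."""
    from probimmune import ModelParams

    return ModelParams(t0=1000, N=1000, n_star=5, K=20, s=0.05)


@pytest.fixture
def two_self_env():
    from probimmune import make_environment

    return make_environment([0.5, 0.5])
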