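import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_healthy_params():
    """A healthy-colon phantom small enough for fast unit tests."""
    from srh import PhantomParams

    return PhantomParams.preset(
        "healthy", field_size_um=300, pixel_size_um=1.0,
        crypt_density_per_mm2=40.0, seed=5,
    )
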