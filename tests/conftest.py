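import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from facesym.cohort import CohortSpec

settings.register_profile(
    "facesym",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("facesym")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_spec():
    """Study conditions without tracker noise or camera jitter: the regime in
    which the asymmetry index equals the assigned severity analytically."""
    return CohortSpec(
        noise_sigma=0.0,
        jitter_scale=0.0,
        jitter_rotation_deg=0.0,
        jitter_translation_px=0.0,
        n_rest=3,
        n_motion=5,
    )
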