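import numpy as np
import pytest
from hypothesis import settings

from punchlab import synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

ZERO_NOISE = dict(accel_noise_g=0.0, gyro_noise_dps=0.0, force_noise_frac=0.0)


@pytest.fixture(scope="session")
def elite_profile():
    return synthetic.make_cohort(1, (0.9, 1.0), seed=11)[0]


@pytest.fixture(scope="session")
def clean_session(elite_profile):
    """A 500-punch zero-noise elite session shared across recovery tests."""
    return synthetic.simulate_session(elite_profile, 500, seed=3, **ZERO_NOISE)


@pytest.fixture(scope="session")
def clean_punch(elite_profile):
    rng = np.random.default_rng(1)
    return synthetic.simulate_punch(elite_profile, rng, **ZERO_NOISE)
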