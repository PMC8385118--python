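import numpy as np
import pytest

from imvest.synthetic_data import gen_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_stress_cohort():
    """8+8 participants, full effect; shared across tests (read-only)."""
    return gen_cohort(8, 8, theta=1.0, seed=42)


@pytest.fixture(scope="session")
def small_null_cohort():
    """8+8 participants, no group effect; shared across tests (read-only)."""
    return gen_cohort(8, 8, theta=0.0, seed=42)
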