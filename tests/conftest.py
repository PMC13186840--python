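import numpy as np
import pytest
from hypothesis import settings

from hurstlab import CohortConfig, generate_cohort, simulate_fgn

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def persistent_series():
    """A short persistent fGn series (H = 0.75, 64 strides)."""
    return simulate_fgn(0.75, 64, seed=421)


@pytest.fixture(scope="session")
def small_cohort():
    """One-group cohort: 12 subjects, 2 days x 9 trials, 60 strides."""
    config = CohortConfig(
        groups={"young": 0.75},
        n_subjects=12,
        n_strides=60,
        sd_subject=0.10,
        sd_day=0.04,
        sd_trial=0.03,
        seed=7,
    )
    cohort, truth = generate_cohort(config)
    return config, cohort, truth
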