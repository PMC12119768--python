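import numpy as np
import pytest

from asdscreen.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 426-subject cohort (observed participation pattern)."""
    return generate_cohort(seed=7)


@pytest.fixture(scope="session")
def large_cohort():
    """A 5000-subject cohort with everyone observed at both acute waves."""
    config = SyntheticConfig(
        n_subjects=5000, w1_only=0, w2_only=0, both_waves=5000, seed=11
    )
    return generate_cohort(config, calibration_n=50_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20240814)
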