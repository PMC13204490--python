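import numpy as np
import pytest

from s2cfl import CohortConfig, PreprocessConfig, generate_cohort
from s2cfl.preprocess import preprocess_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny default-effect cohort (raw signals, 300 s episodes)."""
    return generate_cohort(CohortConfig(n_subjects=6, episodes_per_subject=3, duration_s=300, seed=42))


@pytest.fixture(scope="session")
def processed_small(small_cohort):
    records, dropped = preprocess_cohort(small_cohort, PreprocessConfig(min_duration_s=300))
    assert not dropped
    return records


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
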