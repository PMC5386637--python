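import numpy as np
import pandas as pd
import pytest

from survscreen.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort shared across read-only tests."""
    return simulate_cohort(CohortConfig(n_samples=466, n_features=200, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_survival(rng, n, scale=100.0, censor_frac=0.3):
    """Small random survival dataset for oracle comparisons."""
    time = rng.exponential(scale, n) + 0.5
    event = (rng.random(n) > censor_frac).astype(int)
    # duplicate a few times to exercise tie handling
    k = max(1, n // 5)
    time[:k] = np.round(time[:k])
    time = np.maximum(time, 0.5)
    return time, event
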