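import numpy as np
import pytest

from neopcg import SimulationParams, extract_cohort_features, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12 healthy / 8 PDA / 4 CHD patients with the default strong murmur."""
    return simulate_cohort(12, 8, 4, SimulationParams(), seed=101)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return extract_cohort_features(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
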