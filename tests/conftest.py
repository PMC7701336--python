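import numpy as np
import pytest

from cardioclust.simulate import SimConfig, simulate_cohort
from cardioclust.screening import screen_features


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized synthetic cohort (latent truth, features, reference)."""
    return simulate_cohort(SimConfig(seed=7))


@pytest.fixture(scope="session")
def features(default_cohort):
    return default_cohort[1]


@pytest.fixture(scope="session")
def latent(default_cohort):
    return default_cohort[0]


@pytest.fixture(scope="session")
def ground_truth(default_cohort):
    return default_cohort[2]


@pytest.fixture(scope="session")
def screening_report(features):
    """Screening of the default cohort (MIC matrix computed once per session)."""
    return screen_features(features)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
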