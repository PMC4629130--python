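import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cimexolf as co
from cimexolf.presets import build_profiles, default_archetypes, reference_matrix

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset():
    return default_archetypes()


@pytest.fixture(scope="session")
def ref_matrix(preset):
    """Noise-free matrix of the configured reference-dose rates."""
    return reference_matrix(preset)


@pytest.fixture(scope="session")
def sim_matrix(preset):
    """Full simulated 104 x 6 response matrix (6 replicates, fixed seed)."""
    profiles, classes = build_profiles(preset)
    matrix, records = co.gen_response_matrix(
        profiles, classes, n_replicates=6, seed=7
    )
    return matrix


def random_train(seed: int, rate: float = 30.0, duration: float = 3.0):
    """Homogeneous Poisson spike train helper (no refractory)."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    times = np.unique(rng.uniform(0.0, duration, n))
    return co.SpikeTrain(times, duration)


def toy_matrix(values, classes=None, index=None):
    """Build a ResponseMatrix straight from a dict/DataFrame of means."""
    mean = pd.DataFrame(values, dtype=float, index=index)
    if classes is None:
        classes = pd.Series("aldehyde", index=mean.index)
    else:
        classes = pd.Series(classes)
    zeros = mean * 0.0
    return co.ResponseMatrix(mean, zeros, (zeros + 6).astype(int), classes)
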