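import numpy as np
import pytest

from gaitspeed.features import WindowSpec, build_feature_matrix
from gaitspeed.simulate import (ProtocolSpec, default_protocol, sample_cohort,
                                simulate_protocol)

FS = 50.0


@pytest.fixture(scope="session")
def profile():
    return sample_cohort(1, seed=7)[0]


@pytest.fixture(scope="session")
def short_protocol():
    """Study-shaped protocol with 30-s bouts: fast enough for unit tests."""
    return default_protocol(bout_duration=30.0)


@pytest.fixture(scope="session")
def short_set(profile, short_protocol):
    return simulate_protocol(profile, short_protocol, FS)


@pytest.fixture(scope="session")
def cohort4_sets(short_protocol):
    cohort = sample_cohort(4, seed=11)
    return [simulate_protocol(p, short_protocol, FS) for p in cohort]


@pytest.fixture(scope="session")
def cohort4_features(cohort4_sets):
    return build_feature_matrix(cohort4_sets, "dual", WindowSpec(3.0))


def random_window(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Random but gait-like window: gravity + sine mixture + noise."""
    t = np.arange(n) / fs
    arr = np.empty((n, 3))
    for ax in range(3):
        sig = rng.normal(0.8, 0.3)
        for _ in range(rng.integers(0, 4)):
            f = rng.uniform(0.5, 12.0)
            sig = sig + rng.uniform(0.05, 0.6) * np.sin(2 * np.pi * f * t + rng.uniform(0, 6.28))
        arr[:, ax] = sig + rng.normal(0, rng.uniform(0, 0.1), n)
    return arr
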