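"""Shared fixtures: one full simulated study reused across the suite."""

import numpy as np
import pytest

import sleepuq as s


@pytest.fixture(scope="session")
def study() -> s.StudyResult:
    """A complete simulated study: 4 training + 10 test nights, 960 epochs each.

    Severity-stratified fragmentation (4 normal / 2 mild / 2 moderate /
    2 severe test nights), KDE-HMM stager, Shannon-entropy flagging at
    1 bit.  Built once per session (~1 min) and shared by every end-to-end
    test.
    """
    return s.run_study(s.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def small_night():
    """One short simulated night with features, for cheap model tests."""
    config = s.SyntheticStudyConfig(n_epochs=150, seed=11)
    hypnogram, features = s.simulate_and_featurize(config)
    return config, hypnogram, features


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210930)


def random_simplex(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Draw n points uniformly (Dirichlet(1)) from the 5-class simplex."""
    return rng.dirichlet(np.ones(5), size=n)
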