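import numpy as np
import pytest

from dtfnet import SimSpec, TrialSet, make_two_class_trialset


@pytest.fixture(scope="session")
def small_trialset() -> TrialSet:
    """A light 10-channel two-class set (12 trials/class, 1.5 s) for unit tests."""
    ts, _ = make_two_class_trialset(
        SimSpec(seed=42, n_trials_per_class=12, trial_seconds=1.5)
    )
    return ts


@pytest.fixture(scope="session")
def small_trialset_with_gt():
    """Default-geometry set (40 trials/class, 6 s) plus analytic ground truth."""
    return make_two_class_trialset(SimSpec(seed=42))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
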