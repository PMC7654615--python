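import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rarecenter import TrialData

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def toy_trial():
    """Fixed 3-center x 6-subject trial used by the matrix-oracle tests."""
    center = np.repeat([1, 2, 3], 6)
    arm = np.tile([0, 0, 0, 1, 1, 1], 3)
    outcome = np.array([0, 1, 0, 1, 1, 0,
                        1, 0, 0, 1, 1, 1,
                        0, 0, 0, 1, 0, 1])
    return TrialData(center, arm, outcome)


def make_two_by_two(a, b, c, d, center=1):
    """A single-center trial with the given 2x2 cell counts."""
    arm = np.concatenate([np.ones(a + b, int), np.zeros(c + d, int)])
    outcome = np.concatenate([
        np.ones(a, int), np.zeros(b, int), np.ones(c, int), np.zeros(d, int)])
    return TrialData(np.full(arm.size, center), arm, outcome)
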