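import numpy as np
import pytest

from ecelab import LRSet, SimSpec, simulate_calibrated


@pytest.fixture
def two_trial_set():
    """One theta1 trial at LR=10, one theta2 trial at LR=0.1 (symmetric)."""
    return LRSet(np.log([10.0, 0.1]), [1, 0])


@pytest.fixture
def three_trial_set():
    """theta1 LRs {10, 0.1}, theta2 LR {0.5}: one false rejection at tau=1."""
    return LRSet(np.log([10.0, 0.1, 0.5]), [1, 1, 0])


@pytest.fixture
def neutral_set():
    """All LR = 1: the neutral (useless but honest) system."""
    return LRSet(np.zeros(6), [1, 1, 1, 0, 0, 0])


@pytest.fixture
def oracle_set():
    """Certain and correct on every trial."""
    return LRSet([np.inf, np.inf, -np.inf, -np.inf], [1, 1, 0, 0])


@pytest.fixture(scope="session")
def big_calibrated_set():
    """Well-calibrated Gaussian set, sigma^2=4, 5e4 trials/class."""
    return simulate_calibrated(SimSpec(sigma2=4.0, n1=50_000, n2=50_000, seed=20))


def random_lr_set(rng, n_max=30, infinities=False):
    """A random LR set with at least one trial per class."""
    n = int(rng.integers(2, n_max + 1))
    llr = rng.normal(0.0, 3.0, n)
    label = np.zeros(n, dtype=int)
    label[: max(1, int(rng.integers(1, n)))] = 1
    rng.shuffle(label)
    if label.sum() == 0:
        label[0] = 1
    if label.sum() == n:
        label[0] = 0
    return LRSet(llr, label)
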