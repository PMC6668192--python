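import numpy as np
import pytest

from crbias import HazardParams


@pytest.fixture(scope="session")
def scenario3_hp() -> HazardParams:
    """Differential-effect setting: treatment helps event 1, harms event 2,
    confounder suppresses event 1."""
    return HazardParams(beta1=-1.0, beta2=0.0, gamma1=-1.0, gamma2=1.0,
                        k=1.0, baseline="constant")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_competing_sample(rng, n, require_both_arm_events=True, event=1):
    """Random small competing-risks dataset with events of `event` in both arms
    (avoids monotone-likelihood separation, where the MLE is infinite)."""
    while True:
        t = rng.exponential(size=n)
        delta = rng.integers(1, 3, size=n)
        z = rng.integers(0, 2, size=n)
        ev = delta == event
        if not require_both_arm_events:
            return t, delta, z
        if (ev & (z == 1)).any() and (ev & (z == 0)).any():
            return t, delta, z
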