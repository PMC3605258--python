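import numpy as np
import pytest

from survcut import SurvivalData, preset, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20130306 % 2**16)


@pytest.fixture
def toy_survival():
    """Twelve cases, mixed events and censoring, two groups of six."""
    rng = np.random.default_rng(7)
    time = np.round(rng.exponential(24, 12) + 0.5, 1)
    event = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1])
    return SurvivalData(time, event)


@pytest.fixture(scope="session")
def validation_like_cohort():
    return simulate_cohort(preset("validation-like"), seed=11)


@pytest.fixture(scope="session")
def training_like_cohort():
    return simulate_cohort(preset("training-like"), seed=5)


def random_survival(rng, n, event_rate=0.7, tie_prob=0.0):
    """Small random right-censored dataset, optionally with tied times."""
    time = rng.exponential(20, n) + 0.5  # shift keeps times positive, no clipping ties
    if tie_prob > 0:
        time = np.ceil(time)  # integer times force ties
    event = (rng.random(n) < event_rate).astype(int)
    if event.sum() == 0:
        event[rng.integers(n)] = 1
    return SurvivalData(time, event)
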