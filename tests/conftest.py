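import numpy as np
import pytest

from markercut import MarkerDataset
from markercut.simulate import MixtureSpec, cohort_dataset, gen_bimodal_marker, make_cohort


def make_dataset(marker, outcome=None, time=None, event=None):
    return MarkerDataset(
        marker=np.asarray(marker, dtype=float),
        outcome=None if outcome is None else np.asarray(outcome, dtype=bool),
        time=None if time is None else np.asarray(time, dtype=float),
        event=None if event is None else np.asarray(event, dtype=int),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def bimodal_marker():
    """Well-separated bimodal sample for mixture fitting."""
    return gen_bimodal_marker(800, MixtureSpec(pi1=0.5, mu1=0.0, mu2=4.0, sigma1=1.0, sigma2=1.0), seed=11)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort: marker + binary status + survival."""
    return cohort_dataset(make_cohort(n=200, seed=5))


@pytest.fixture
def random_survival(rng):
    """Small survival dataset with ties and censoring."""
    n = 40
    times = np.round(rng.exponential(5, n), 1) + 0.1
    events = (rng.random(n) < 0.7).astype(int)
    groups = rng.random(n) < 0.5
    return times, events, groups
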