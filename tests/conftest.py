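import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iwamle import CensoringScheme, datasets

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ball_bearings_complete():
    return datasets.ball_bearings()


@pytest.fixture(scope="session")
def ball_bearings_censored(ball_bearings_complete):
    return ball_bearings_complete.restrict(datasets.scheme_preset("ball-bearings-censored"))


@pytest.fixture(scope="session")
def flood_complete():
    return datasets.flood_levels()


@pytest.fixture(scope="session")
def flood_censored(flood_complete):
    return flood_complete.restrict(datasets.scheme_preset("flood-levels-censored"))


def random_scheme(rng, max_n=200, min_s=2):
    """A random valid multiply type-II censoring scheme."""
    n = int(rng.integers(min_s, max_n + 1))
    s = int(rng.integers(min_s, n + 1))
    ranks = np.sort(rng.choice(np.arange(1, n + 1), size=s, replace=False))
    return CensoringScheme(n, ranks)
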