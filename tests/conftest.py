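import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emgelbow as eg
from emgelbow.muscle import default_params
from emgelbow.skeletal import SkeletalParameters
from emgelbow.timeseries import TimeSeries

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def biceps():
    return default_params("biceps")


@pytest.fixture(scope="session")
def triceps():
    return default_params("triceps")


@pytest.fixture(scope="session")
def skeletal():
    return SkeletalParameters(body_mass=70.0, forearm_length=0.25)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def smooth_drive(
    rng: np.random.Generator,
    duration: float = 6.0,
    rate: float = 100.0,
    lo: float = 0.0,
    hi: float = 0.9,
    n_bumps: int = 3,
) -> TimeSeries:
    """A smooth, band-limited random drive in [lo, hi] for recovery tests."""
    n = int(duration * rate) + 1
    t = np.arange(n) / rate
    x = np.zeros(n)
    for _ in range(n_bumps):
        centre = rng.uniform(0.15, 0.85) * duration
        width = rng.uniform(0.4, 1.2)
        height = rng.uniform(0.3, 1.0)
        x += height * np.exp(-0.5 * ((t - centre) / width) ** 2)
    x = x / x.max()
    return TimeSeries(0.0, rate, lo + (hi - lo) * x, "dimensionless")


@pytest.fixture(scope="session")
def tiny_cohort():
    """One noiseless subject, shared by read-only tests."""
    return eg.generate_cohort(1, seed=11, emg_noise=False)
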