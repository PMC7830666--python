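import numpy as np
import pytest

import multichaos as mc


@pytest.fixture(scope="session")
def logistic_series() -> mc.TimeSeries:
    """A 5000-point chaotic logistic-map orbit (mu = 4), seeded."""
    return mc.simulate("logistic", n_samples=5000, seed=7)


@pytest.fixture(scope="session")
def henon_series() -> mc.TimeSeries:
    return mc.simulate("henon", n_samples=5000, seed=7)


@pytest.fixture(scope="session")
def sine_series() -> mc.TimeSeries:
    """A noiseless sine of period 40 samples."""
    t = np.arange(2000)
    return mc.TimeSeries(np.sin(2 * np.pi * t / 40.0), dt=1.0)


@pytest.fixture(scope="session")
def noise_series() -> mc.TimeSeries:
    """I.i.d. Gaussian noise, 5000 samples."""
    rng = np.random.default_rng(11)
    return mc.TimeSeries(rng.normal(size=5000), dt=1.0)
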