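import numpy as np
import pytest

from oclab import KMORConfig, generate, preset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def blob_outliers():
    """Unit-sd blob of 100 with 5 planted 10-sigma outliers + ground truth."""
    return generate(preset("blob-outliers", seed=7))


@pytest.fixture
def two_blobs():
    """Two tight blobs (sd 0.2) 10 apart, 100 points total."""
    return generate(preset("two-blobs", seed=7))


@pytest.fixture
def separable():
    """Two target clusters + minority offset 10 sigma, 300 rows."""
    return generate(preset("separable", seed=7))


@pytest.fixture
def kmor_config():
    return KMORConfig(k=1, gamma=2.5, n0_fraction=0.05, seed=0)


def write_keel(tmp_path, text, name="data.dat"):
    path = tmp_path / name
    path.write_text(text)
    return path
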