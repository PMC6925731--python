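import numpy as np
import pytest

from carostab import ultrasim


@pytest.fixture(scope="session")
def speckle_image():
    """One rendered B-mode frame of a flat phantom (fully developed speckle)."""
    rc = ultrasim.RenderConfig(shape=(96, 96))
    ph = ultrasim.make_phantom(0.6, None, 30000, 11, extent_mm=(4.8, 4.8))
    return ultrasim.render_bmode(ph, rc).astype(float) + 1.0


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small simulated dataset shared by integration-level tests."""
    return ultrasim.simulate_dataset("tiny", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
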