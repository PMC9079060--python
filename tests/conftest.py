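import numpy as np
import pytest

from sinuseg.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """One deterministic noise-free phantom with ostium and lining."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, thickening_mm=1.2, seed=4))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
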