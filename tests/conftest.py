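import numpy as np
import pytest

from cryoseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom mouse at the default (quarter-scale) size."""
    return generate_phantom(PhantomSpec(seed=5))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise/texture-free phantom: exact colors, useful for contrast checks."""
    return generate_phantom(PhantomSpec(seed=5, noise_sd=0.0, texture_amplitude=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
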