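import numpy as np
import pytest

from burnscope import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """One 64x64 phantom image + ground-truth mask (seeded)."""
    return generate_phantom(PhantomSpec(size=(64, 64), seed=42))


@pytest.fixture(scope="session")
def two_blob_values():
    """Scalar intensities from two tight, well-separated populations."""
    g = np.random.default_rng(7)
    return np.concatenate([10 + g.normal(0, 1, 500), 200 + g.normal(0, 1, 500)])
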