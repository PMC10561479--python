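import numpy as np
import pytest

from dmfnet.phantom import PhantomSpec, generate_phantoms


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantoms():
    """Sixteen 32x32 phantoms for fast training/evaluation tests."""
    return generate_phantoms(16, PhantomSpec(size=32, background_smoothness=3.0), seed=42)


@pytest.fixture(scope="session")
def phantom_128():
    return generate_phantoms(1, PhantomSpec(), seed=5)[0]
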