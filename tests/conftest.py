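import numpy as np
import pytest

from denobench.noise import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom():
    """256x256 piecewise-constant ellipse phantom (plateaus + sharp edges)."""
    return make_phantom(PhantomSpec(kind="shepp_like", size=(256, 256)))


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
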