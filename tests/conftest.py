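import numpy as np
import pytest

from eunet.data import PhantomConfig, generate_phantoms


@pytest.fixture(scope="session")
def tiny_cell_set():
    """Four 32x32 cell phantoms: the standard overfit-capacity fixture."""
    return generate_phantoms(PhantomConfig(mode="cell", count=4, size=(32, 32), seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
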