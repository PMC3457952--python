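import numpy as np
import pytest

from volepom import VoleParams, generate_landscape
from volepom.landscape import VegetationState


@pytest.fixture
def params():
    return VoleParams()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_block():
    """Tiny grassland block in a dispersal-only surround (fast to simulate)."""
    return generate_landscape("homogeneous_block", dims=60)


@pytest.fixture
def grown_vegetation():
    """Single-patch vegetation at full new-green quality (digestibility 1)."""
    def make(n_patches: int = 1):
        veg = VegetationState.zeros(n_patches)
        veg.ring[:] = 1.0
        veg.total[:] = veg.ring.sum(axis=1)
        return veg
    return make
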