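import numpy as np
import pytest

from boxsup3d import PhantomSpec, box_from_mask, generate_phantom, normalize_volume


@pytest.fixture(scope="session")
def phantom():
    """One deterministic phantom with its mask and derived tight box."""
    vol, mask = generate_phantom(PhantomSpec(seed=42))
    return vol, mask, box_from_mask(mask)


@pytest.fixture(scope="session")
def normalized_phantom(phantom):
    vol, mask, box = phantom
    return normalize_volume(vol), mask, box


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
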