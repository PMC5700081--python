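import numpy as np
import pytest

import dreammachine as dm


@pytest.fixture(scope="session")
def toy_net():
    """Default seeded toy network (zero 'same' padding)."""
    return dm.default_toy_net(seed=0)


@pytest.fixture(scope="session")
def wrap_net():
    """Toy network with cyclic padding: exactly shift-equivariant."""
    return dm.default_toy_net(seed=0, pad_mode="wrap")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noise_image():
    """Seeded 32x32 mid-range noise image on the [0, 255] working range."""
    return np.random.default_rng(7).uniform(40.0, 215.0, (32, 32, 3))


@pytest.fixture(scope="session")
def synthetic_video():
    """8 frames, 64x64, patch translating by (dx, dy) = (3, 0) per frame."""
    spec = dm.SyntheticVideoSpec()
    frames, flows = dm.generate_synthetic_video(spec)
    return spec, frames, flows
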