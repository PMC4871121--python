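import numpy as np
import pytest

from igrtqa import PhantomSpec, RigidTransform2D, make_pair


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """Well-conditioned 128x128 phantom pair with a known (5, -3, 2 deg) truth."""
    spec = PhantomSpec(
        shape=(128, 128),
        truth=RigidTransform2D(5.0, -3.0, 2.0),
        gamma=1.5,
        noise_sigma=0.01,
        seed=1,
    )
    return make_pair(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, degradation-free phantom pair (moving = shifted rendering)."""
    spec = PhantomSpec(
        shape=(128, 128),
        truth=RigidTransform2D(5.0, -3.0, 0.0),
        gamma=1.0,
        contrast=1.0,
        offset=0.0,
        noise_sigma=0.0,
        seed=0,
    )
    return make_pair(spec)
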