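import numpy as np
import pytest

from wormswarm import ModelParams, npr1_reference


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A small, fast parameter set for unit tests."""
    return ModelParams(N=8, M=6, arena_side=4.0, seed=3)


@pytest.fixture
def npr1():
    return npr1_reference()


def chain_lengths(skeletons: np.ndarray, side: float) -> np.ndarray:
    """Total chain length per worm per frame from wrapped skeletons."""
    d = np.diff(skeletons, axis=-2)
    d -= side * np.round(d / side)
    return np.hypot(d[..., 0], d[..., 1]).sum(axis=-1)
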