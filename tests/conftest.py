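import numpy as np
import pytest

from mataging.containers import BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sierpinski_carpet(depth: int) -> np.ndarray:
    """Boolean Sierpinski-carpet iterate of side 3**depth."""
    a = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        a = np.block([[a, a, a], [a, np.zeros_like(a), a], [a, a, a]])
    return a


def random_puncta_mask(rng, shape=(3, 64, 64), n=60) -> BinaryMask:
    """Mask of n single-voxel puncta placed uniformly at random."""
    m = np.zeros(shape, dtype=bool)
    m[
        rng.integers(0, shape[0], n),
        rng.integers(0, shape[1], n),
        rng.integers(0, shape[2], n),
    ] = True
    return BinaryMask(m)
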