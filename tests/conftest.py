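import numpy as np
import pytest

from dropsight.geometry import BinaryMask
from dropsight.synthetic import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """A compact scene with a guaranteed crystal count, shared across tests."""
    spec = SceneSpec(
        image_height=128,
        image_width=160,
        drop_axes=(60.0, 48.0),
        crystal_count_range=(3, 3),
        crystal_size_range=(8.0, 24.0),
        seed=7,
    )
    return generate_scene(spec)


def random_mask(rng, height, width, p=0.3) -> BinaryMask:
    return BinaryMask(rng.uniform(size=(height, width)) < p)


def brute_force_edt(mask: BinaryMask) -> np.ndarray:
    """O(N^2) exact Euclidean distance transform oracle.

    For every foreground pixel, the minimum Euclidean distance over all
    background pixels, with the image border padded by background.
    """
    padded = np.pad(mask.array, 1, mode="constant", constant_values=False)
    bg = np.argwhere(~padded).astype(float)
    fg = np.argwhere(padded).astype(float)
    out = np.zeros(padded.shape, dtype=float)
    if len(fg):
        d2 = (
            (fg[:, None, 0] - bg[None, :, 0]) ** 2
            + (fg[:, None, 1] - bg[None, :, 1]) ** 2
        )
        out[padded] = np.sqrt(d2.min(axis=1))
    return out[1:-1, 1:-1]
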