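import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from osteotex import GreyImage, TextureParams, default_class_params, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_image(rng, shape=(8, 8), max_intensity=255.0):
    return GreyImage(
        pixels=rng.uniform(0.0, max_intensity, size=shape), max_intensity=max_intensity
    )


@pytest.fixture
def step_image():
    """Two-level vertical step: left half 0, right half 100."""
    px = np.zeros((8, 8))
    px[:, 4:] = 100.0
    return GreyImage(pixels=px, max_intensity=255.0)


@pytest.fixture(scope="session")
def small_two_class_dataset():
    """20 images/class at 32x32 — fast enough for training smoke tests."""
    params = default_class_params(2, size=(32, 32))
    return gen_dataset(params, n_per_class=20, seed=9)
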