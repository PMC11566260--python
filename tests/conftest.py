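import numpy as np
import pytest

from fgscontrast import ModalityImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_image():
    """A 40x60 constant image, pitch 0.1 mm/px."""
    return ModalityImage(np.full((40, 60), 5.0), 0.1)


@pytest.fixture
def half_plane():
    """A 50x80 step scene: tumor (value 130) in columns < 40, bg 100.

    Returns (image, tumor_mask); the analytic border lies at column 39.5.
    """
    data = np.full((50, 80), 100.0)
    data[:, :40] = 130.0
    mask = np.zeros((50, 80), dtype=bool)
    mask[:, :40] = True
    return ModalityImage(data, 0.1), mask
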