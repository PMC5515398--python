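import numpy as np
import pytest

from virtualrig.stackio import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_gray_stack(rng):
    """10-frame random 8-bit grayscale stack."""
    return ImageStack(
        frames=rng.integers(0, 256, size=(10, 16, 12), dtype=np.uint8),
        frame_rate_hz=42.0,
        pixel_size_um=1.0,
    )


@pytest.fixture
def small_rgb_stack(rng):
    return ImageStack(
        frames=rng.integers(0, 256, size=(6, 8, 10, 3), dtype=np.uint8),
        frame_rate_hz=42.0,
        pixel_size_um=2.0,
    )
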