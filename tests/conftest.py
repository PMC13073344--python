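import numpy as np
import pytest


def make_disk(diameter_px: float, pad: int = 3) -> np.ndarray:
    """Digital disk by pixel-center inclusion (the rendering convention)."""
    n = int(np.ceil(diameter_px)) + 2 * pad
    yy, xx = np.mgrid[0:n, 0:n]
    c = n / 2.0
    return (xx + 0.5 - c) ** 2 + (yy + 0.5 - c) ** 2 <= (diameter_px / 2.0) ** 2


def make_rect(h: int, w: int, pad: int = 3) -> np.ndarray:
    m = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    m[pad:pad + h, pad:pad + w] = True
    return m


@pytest.fixture
def disk100():
    return make_disk(100)


@pytest.fixture
def flat_image():
    """Constant-intensity image factory matching a mask's shape."""

    def _make(mask, level=50.0):
        return np.full(mask.shape, level, dtype=float)

    return _make
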