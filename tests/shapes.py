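"""Analytic binary shapes used as ground truth across the test suite."""

import numpy as np
from skimage import draw


def disk_mask(radius: int, pad: int = 10) -> np.ndarray:
    n = 2 * radius + 2 * pad
    img = np.zeros((n, n), dtype=bool)
    rr, cc = draw.disk((n / 2 - 0.5, n / 2 - 0.5), radius, shape=img.shape)
    img[rr, cc] = True
    return img


def square_mask(side: int, pad: int = 10) -> np.ndarray:
    n = side + 2 * pad
    img = np.zeros((n, n), dtype=bool)
    img[pad : pad + side, pad : pad + side] = True
    return img


def annulus_mask(outer: int, inner: int, pad: int = 10) -> np.ndarray:
    n = 2 * outer + 2 * pad
    img = np.zeros((n, n), dtype=bool)
    c = (n / 2 - 0.5, n / 2 - 0.5)
    rr, cc = draw.disk(c, outer, shape=img.shape)
    img[rr, cc] = True
    rr, cc = draw.disk(c, inner, shape=img.shape)
    img[rr, cc] = False
    return img


def centered_disk_glyph(radius: int = 120, canvas: int = 500) -> np.ndarray:
    """Disk centered on the 500×500 canvas (cut line bisects it)."""
    img = np.zeros((canvas, canvas), dtype=bool)
    rr, cc = draw.disk((canvas / 2 - 0.5, canvas / 2 - 0.5), radius, shape=img.shape)
    img[rr, cc] = True
    return img
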