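import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20160504)


def make_disk_mask(side: int, radius: float, center=None) -> np.ndarray:
    """Digital disk: pixel centers within `radius` of the center."""
    cx = cy = (side - 1) / 2.0 if center is None else None
    if center is not None:
        cx, cy = center
    yy, xx = np.mgrid[0:side, 0:side]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def sierpinski_carpet(depth: int) -> np.ndarray:
    """Depth-d Sierpinski carpet on a 3^d grid (True = retained)."""
    m = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        n = m.shape[0]
        out = np.zeros((3 * n, 3 * n), dtype=bool)
        for i in range(3):
            for j in range(3):
                if (i, j) != (1, 1):
                    out[i * n : (i + 1) * n, j * n : (j + 1) * n] = m
        m = out
    return m
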