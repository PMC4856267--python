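"""Box-counting fractal dimension and gliding-box lacunarity.

The fractal dimension measures the space-filling complexity of the binarized
mucosal pattern: N(s), the number of s x s grid boxes containing at least one
foreground pixel, scales as s^-D for a fractal of dimension D, so D is the
least-squares slope of log N(s) against log(1/s).  Grid boxes are anchored at
the top-left corner and partial boxes along the right/bottom edges are
included, so no pixel margin is ever discarded.

Lacunarity quantifies gap structure.  For box size r, an r x r window glides
over every position; with M1 and M2 the first and second moments of the
window-mass distribution, Lambda(r) = M2 / M1^2 >= 1, with equality for
translation-invariant mass.  The reported scalar is the mean of
Lambda(r) - 1 over the configured box sizes, hence 0 for a uniform pattern
and larger for gappier ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .config import FractalConfig, dyadic_scales, parse_threshold_spec, validate_scales
from .errors import DegenerateInputError, ParameterError
from .io import GrayImage


@dataclass
class BinaryImage:
    """Boolean foreground mask plus the threshold that produced it."""

    mask: np.ndarray
    threshold_used: float

    @property
    def shape(self):
        return self.mask.shape


@dataclass
class FractalResult:
    fractal_dimension: float
    lacunarity: float
    scales_used: tuple[int, ...]
    fit_r2: float


def binarize_otsu(image: GrayImage | np.ndarray) -> BinaryImage:
    """Binarize by Otsu's criterion over a 256-bin histogram.

    Foreground is intensity strictly above the threshold.
    """
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    if np.unique(pixels).size < 2:
        raise DegenerateInputError("constant image cannot be thresholded")
    t = float(threshold_otsu(pixels, nbins=256))
    return BinaryImage(mask=pixels > t, threshold_used=t)


def binarize(image: GrayImage | np.ndarray, method: str = "otsu") -> BinaryImage:
    """Binarize with ``"otsu"`` or a fixed threshold ``"fixed:<t>"``."""
    t = parse_threshold_spec(method)
    if t is None:
        return binarize_otsu(image)
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    return BinaryImage(mask=pixels > t, threshold_used=t)


def box_occupancy(mask: np.ndarray, scale: int) -> int:
    """N(s): occupied s x s boxes on the top-left anchored grid."""
    h, w = mask.shape
    ph = (-h) % scale
    pw = (-w) % scale
    padded = np.pad(mask, ((0, ph), (0, pw)), constant_values=False)
    blocks = padded.reshape(padded.shape[0] // scale, scale, padded.shape[1] // scale, scale)
    return int(blocks.any(axis=(1, 3)).sum())


def box_count_dimension(
    mask: BinaryImage | np.ndarray, scales: Sequence[int] | None = None
) -> FractalResult:
    """Estimate the box-counting dimension of a binary mask.

    ``scales=None`` selects dyadic sizes 2..side/4.  Scales where N(s) = 0
    cannot occur for a nonempty mask; scales larger than half the short side
    are rejected because they leave too few boxes for a stable fit.
    """
    m = mask.mask if isinstance(mask, BinaryImage) else np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ParameterError("mask must be 2-D")
    if not m.any():
        raise DegenerateInputError("empty mask has no box-counting dimension")
    side = min(m.shape)
    scales_t = dyadic_scales(side) if scales is None else validate_scales(scales, side)
    counts = np.array([box_occupancy(m, s) for s in scales_t], dtype=np.float64)
    x = np.log(1.0 / np.asarray(scales_t, dtype=np.float64))
    y = np.log(counts)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    # lacunarity is computed separately; not populated here
    return FractalResult(
        fractal_dimension=float(slope),
        lacunarity=float("nan"),
        scales_used=scales_t,
        fit_r2=r2,
    )


def _window_sums(mask01: np.ndarray, r: int) -> np.ndarray:
    """Exact integer sums of every r x r window (integral-image trick)."""
    s = np.zeros((mask01.shape[0] + 1, mask01.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask01, axis=0), axis=1, out=s[1:, 1:])
    return s[r:, r:] - s[:-r, r:] - s[r:, :-r] + s[:-r, :-r]


def gliding_box_lacunarity(
    mask: BinaryImage | np.ndarray, box_sizes: Sequence[int] | None = None
) -> float:
    """Mean of Lambda(r) - 1 over the requested gliding-box sizes."""
    m = mask.mask if isinstance(mask, BinaryImage) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise DegenerateInputError("empty mask: gliding-box first moment is zero")
    sizes = tuple(box_sizes) if box_sizes is not None else FractalConfig().lacunarity_box_sizes
    side = min(m.shape)
    if any(r < 1 or r > side for r in sizes):
        raise ParameterError(f"box sizes must lie in [1, {side}]")
    mask01 = m.astype(np.int64)
    values = []
    for r in sizes:
        masses = _window_sums(mask01, r).astype(np.float64)
        m1 = masses.mean()
        if m1 == 0.0:
            warnings.warn(f"box size {r}: no mass in any window, skipping")
            continue
        m2 = np.mean(masses**2)
        values.append(m2 / (m1 * m1) - 1.0)
    if not values:
        raise DegenerateInputError("no usable box size for lacunarity")
    return float(np.mean(values))


def fractal_parameters(
    mask: BinaryImage | np.ndarray, config: FractalConfig | None = None
) -> FractalResult:
    """Convenience wrapper: FD and lacunarity of one mask per the config."""
    cfg = config or FractalConfig()
    result = box_count_dimension(mask, cfg.scales)
    result.lacunarity = gliding_box_lacunarity(mask, cfg.lacunarity_box_sizes)
    return result
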