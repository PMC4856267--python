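"""Grey-level co-occurrence matrix (GLCM) texture statistics.

The GLCM P(i, j) is the normalized frequency with which a pixel of quantized
grey level i has a neighbour of level j at a fixed displacement (dy, dx).
Four Haralick-style statistics summarize it:

    contrast    = sum (i - j)^2 P(i, j)        local intensity variation
    correlation = sum (i - mu_i)(j - mu_j) P(i, j) / (sigma_i sigma_j)
    energy      = sum P(i, j)^2                texture uniformity
    homogeneity = sum P(i, j) / (1 + |i - j|)  mass near the diagonal

Defaults (8 levels, offset (0, 1), unsymmetrized, per-image range
quantization) mirror the classic toolbox conventions for single-offset
texture scalars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GlcmConfig
from .errors import DegenerateInputError, ParameterError
from .io import GrayImage


@dataclass
class GLCM:
    P: np.ndarray  # levels x levels, normalized to sum 1
    levels: int
    offset: tuple[int, int]


@dataclass
class TextureStats:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float


def quantize(pixels: np.ndarray, levels: int, value_range: str = "image") -> np.ndarray:
    """Linear quantization into ``levels`` equal-width bins.

    ``value_range="image"`` spans the per-image [min, max] (exposure
    invariant); ``"fixed"`` spans [0, 1].
    """
    if value_range == "image":
        lo, hi = float(pixels.min()), float(pixels.max())
    elif value_range == "fixed":
        lo, hi = 0.0, 1.0
    else:
        raise ParameterError(f"unknown quantization range {value_range!r}")
    if hi <= lo:
        raise DegenerateInputError("constant image cannot be quantized")
    q = np.floor((pixels - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def compute_glcm(
    image: GrayImage | np.ndarray,
    levels: int = 8,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = False,
    value_range: str = "image",
) -> GLCM:
    """Count co-occurring quantized grey-level pairs at one displacement."""
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    if levels < 2:
        raise ParameterError("levels must be >= 2")
    dy, dx = int(offset[0]), int(offset[1])
    if (dy, dx) == (0, 0):
        raise ParameterError("offset must be nonzero")
    h, w = pixels.shape
    if abs(dy) >= h or abs(dx) >= w:
        raise ParameterError(f"offset {offset} larger than image {pixels.shape}")
    if np.unique(pixels).size < 2:
        raise DegenerateInputError("constant image: GLCM statistics undefined")
    q = quantize(pixels, levels, value_range)
    r0, r1 = max(0, -dy), h - max(0, dy)
    c0, c1 = max(0, -dx), w - max(0, dx)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dy : r1 + dy, c0 + dx : c1 + dx].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels).reshape(levels, levels)
    counts = counts.astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    return GLCM(P=counts / counts.sum(), levels=levels, offset=(dy, dx))


def glcm_stats(glcm: GLCM) -> TextureStats:
    """Contrast, correlation, energy and homogeneity of one GLCM."""
    P = glcm.P
    L = glcm.levels
    i = np.arange(L, dtype=np.float64)[:, None]
    j = np.arange(L, dtype=np.float64)[None, :]
    contrast = float(np.sum((i - j) ** 2 * P))
    energy = float(np.sum(P**2))
    homogeneity = float(np.sum(P / (1.0 + np.abs(i - j))))
    mu_i = float(np.sum(i * P))
    mu_j = float(np.sum(j * P))
    var_i = float(np.sum((i - mu_i) ** 2 * P))
    var_j = float(np.sum((j - mu_j) ** 2 * P))
    if var_i <= 0.0 or var_j <= 0.0:
        raise DegenerateInputError(
            "zero marginal variance: correlation undefined (constant image upstream)"
        )
    correlation = float(np.sum((i - mu_i) * (j - mu_j) * P) / np.sqrt(var_i * var_j))
    return TextureStats(
        contrast=contrast, correlation=correlation, energy=energy, homogeneity=homogeneity
    )


def texture_parameters(
    image: GrayImage | np.ndarray, config: GlcmConfig | None = None
) -> TextureStats:
    cfg = config or GlcmConfig()
    glcm = compute_glcm(
        image,
        levels=cfg.levels,
        offset=cfg.offset,
        symmetric=cfg.symmetric,
        value_range=cfg.range,
    )
    return glcm_stats(glcm)
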