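"""Per-image feature extraction: the seven-parameter vector.

For each image the pipeline produces, in fixed order: fractal dimension,
lacunarity, contrast, correlation, energy, homogeneity, feature count.  The
texture statistics are computed on the raw intensities; the fractal and
crypt-feature parameters share a single binarization of the Gaussian-smoothed
image (one Otsu pass feeds both, avoiding duplicate work; the modules can be
driven independently through their own APIs when decoupled settings are
needed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .errors import CryptoCADError
from .features import (
    count_round_features,
    effective_ratio_threshold,
    effective_sigma,
    gaussian_smooth,
    marching_squares_contours,
    threshold_binarize,
)
from .fractal import box_count_dimension, gliding_box_lacunarity
from .io import FEATURE_COLUMNS, GrayImage
from .texture import texture_parameters


@dataclass
class FeatureVector:
    """The seven dimensionless image parameters, in canonical order."""

    fractal_dimension: float
    lacunarity: float
    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    feature_count: int

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_COLUMNS], dtype=np.float64)

    @classmethod
    def from_array(cls, arr) -> "FeatureVector":
        vals = dict(zip(FEATURE_COLUMNS, np.asarray(arr, dtype=np.float64)))
        vals["feature_count"] = int(round(vals["feature_count"]))
        return cls(**vals)


def extract_feature_vector(
    image: GrayImage | np.ndarray,
    config: PipelineConfig | None = None,
    image_id: str | None = None,
) -> FeatureVector:
    """Run the full extractor on one image.

    Deterministic: the same image and config always yield the same vector.
    Degenerate inputs (constant images, empty masks) raise with the image id
    attached when one is given.
    """
    cfg = config or PipelineConfig()
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=np.float64)
    try:
        side = min(pixels.shape)
        smoothed = gaussian_smooth(pixels, effective_sigma(cfg.features, side))
        binary = threshold_binarize(smoothed, cfg.features.threshold)

        fd = box_count_dimension(binary, cfg.fractal.scales)
        lac = gliding_box_lacunarity(binary, cfg.fractal.lacunarity_box_sizes)
        tex = texture_parameters(pixels, cfg.glcm)
        # sub-pixel contours: trace the smoothed field at the threshold level
        contours = marching_squares_contours(smoothed, binary.threshold_used)
        feats = count_round_features(
            contours, effective_ratio_threshold(cfg.features, side)
        )
    except CryptoCADError as exc:
        if image_id is not None:
            raise type(exc)(f"image {image_id!r}: {exc}") from exc
        raise
    return FeatureVector(
        fractal_dimension=fd.fractal_dimension,
        lacunarity=lac,
        contrast=tex.contrast,
        correlation=tex.correlation,
        energy=tex.energy,
        homogeneity=tex.homogeneity,
        feature_count=feats.count_round,
    )
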