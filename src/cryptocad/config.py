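"""Pipeline configuration.

Every knob of the feature-extraction pipeline lives here so that a single
object fully determines the mapping image -> feature vector.  Defaults follow
common practice for endomicroscopy texture analysis: dyadic box-counting
scales, gliding-box sizes {2,4,8,16}, an 8-level GLCM at offset (0, 1), and a
roundness cutoff of 4 px expressed at the native 1024x1024 acquisition scale.

Configs can be loaded from a TOML file with tables ``[fractal]``, ``[glcm]``
and ``[features]``.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ParameterError

#: reference image side: thresholds and smoothing widths are expressed at
#: this scale and rescaled proportionally for other image sizes.
REFERENCE_SIDE = 1024


@dataclass(frozen=True)
class FractalConfig:
    """Box-counting and lacunarity settings.

    ``scales=None`` means dyadic sizes 2, 4, 8, ... up to side/4, chosen per
    image.  ``binarization`` is ``"otsu"`` or ``"fixed:<t>"`` with t in [0,1].
    """

    scales: tuple[int, ...] | None = None
    lacunarity_box_sizes: tuple[int, ...] = (2, 4, 8, 16)
    binarization: str = "otsu"


@dataclass(frozen=True)
class GlcmConfig:
    """Grey-level co-occurrence settings.

    ``range="image"`` quantizes over the per-image [min, max]; ``"fixed"``
    uses the full [0, 1] intensity range.
    """

    levels: int = 8
    offset: tuple[int, int] = (0, 1)
    symmetric: bool = False
    range: str = "image"


@dataclass(frozen=True)
class FeaturesConfig:
    """Crypt-feature identification settings.

    ``sigma`` is the Gaussian smoothing width in pixels at the reference
    1024x1024 scale (rescaled proportionally).  ``ratio_threshold`` is the
    area/perimeter cutoff (pixels) above which a closed contour counts as a
    round crypt, likewise expressed at the reference scale; with
    ``rescale_threshold`` the effective cutoff is scaled by side/1024 so the
    same physical geometry is counted at any resolution.
    """

    sigma: float = 2.0
    threshold: str = "otsu"
    ratio_threshold: float = 4.0
    rescale_threshold: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    fractal: FractalConfig = field(default_factory=FractalConfig)
    glcm: GlcmConfig = field(default_factory=GlcmConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, section):
            extra = set(section) - {f.name for f in dataclasses.fields(klass)}
            if extra:
                raise ParameterError(f"unknown config keys: {sorted(extra)}")
            # TOML has no tuples; normalize lists
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
            }
            return klass(**coerced)

        return cls(
            fractal=build(FractalConfig, d.get("fractal", {})),
            glcm=build(GlcmConfig, d.get("glcm", {})),
            features=build(FeaturesConfig, d.get("features", {})),
        )

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def parse_threshold_spec(spec: str) -> float | None:
    """Parse a binarization spec: ``"otsu"`` -> None, ``"fixed:0.4"`` -> 0.4."""
    if spec == "otsu":
        return None
    if spec.startswith("fixed:"):
        try:
            t = float(spec.split(":", 1)[1])
        except ValueError as exc:
            raise ParameterError(f"bad threshold spec {spec!r}") from exc
        if not 0.0 <= t <= 1.0:
            raise ParameterError(f"fixed threshold {t} outside [0, 1]")
        return t
    raise ParameterError(f"unknown binarization method {spec!r}")


def validate_scales(scales: Sequence[int], side: int) -> tuple[int, ...]:
    scales = tuple(int(s) for s in scales)
    if len(set(scales)) < 3:
        raise ParameterError("need at least 3 distinct box-counting scales")
    if any(s < 1 or s > side // 2 for s in scales):
        raise ParameterError(f"scales must lie in [1, side/2] = [1, {side // 2}]")
    return scales


def dyadic_scales(side: int) -> tuple[int, ...]:
    """Default box-counting scales: 2, 4, 8, ... up to side/4."""
    scales = []
    s = 2
    while s <= side // 4:
        scales.append(s)
        s *= 2
    if len(scales) < 3:
        raise ParameterError(f"image side {side} too small for dyadic scales")
    return tuple(scales)
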