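"""Image and table I/O.

Images are held internally as unit-interval float64 arrays regardless of the
source bit depth (one code path for 8- and 16-bit files).  The coordinate
frame is row-major with the origin at the top-left; a pixel's center sits at
integer coordinates, x = column and y = row.  Contour vertices produced
downstream use the same frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: column order of the feature table (fixed; downstream code relies on it)
FEATURE_COLUMNS = (
    "fractal_dimension",
    "lacunarity",
    "contrast",
    "correlation",
    "energy",
    "homogeneity",
    "feature_count",
)

_ACCEPTED_SUFFIXES = {".png", ".tif", ".tiff"}

# ITU-R BT.601 luminance weights, used only when conversion is requested
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class GrayImage:
    """A single-channel image with unit-interval float intensities."""

    pixels: np.ndarray
    bit_depth: int = 8
    source: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def side(self) -> int:
        """Characteristic side length used for resolution rescaling."""
        return min(self.pixels.shape)

    def validate(self) -> "GrayImage":
        p = self.pixels
        if p.ndim != 2:
            raise FormatError(f"expected a 2-D image, got shape {p.shape}")
        if min(p.shape) < 32:
            raise ValidationError(f"image sides must be >= 32, got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValidationError("image contains non-finite intensities")
        return self


def _rescale(arr: np.ndarray) -> tuple[np.ndarray, int]:
    """Map a raw integer/float array onto [0, 1] floats; return bit depth."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0, 8
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0, 16
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(np.float64)
        if out.size and (np.nanmin(out) < 0.0 or np.nanmax(out) > 1.0):
            raise FormatError("float image intensities must already lie in [0, 1]")
        return out, 0
    raise FormatError(f"unsupported pixel dtype {arr.dtype}")


def load_image(path, to_gray: bool = False) -> GrayImage:
    """Read a grayscale PNG or TIFF into a :class:`GrayImage`.

    Multi-channel images are rejected unless ``to_gray`` is set, in which
    case ITU-R 601 luminance conversion is applied.  Silent conversion is
    avoided deliberately: endomicroscopy frames are single-channel, so a
    color file usually signals a data handling mistake.
    """
    path = Path(path)
    if path.suffix.lower() not in _ACCEPTED_SUFFIXES:
        raise FormatError(f"{path.name}: only PNG/TIFF input is supported")
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # unreadable / truncated file
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if raw.ndim == 3:
        if raw.shape[2] == 1:
            raw = raw[:, :, 0]
        elif not to_gray:
            raise FormatError(
                f"{path.name} has {raw.shape[2]} channels; pass to_gray=True "
                "for ITU-R 601 luminance conversion"
            )
        else:
            scaled, depth = _rescale(raw[:, :, :3])
            return GrayImage(scaled @ _LUMA, bit_depth=depth, source=str(path)).validate()
    pixels, depth = _rescale(raw)
    return GrayImage(pixels, bit_depth=depth, source=str(path)).validate()


def save_image(image: GrayImage | np.ndarray, path) -> None:
    """Write a unit-interval image as a 16-bit grayscale PNG/TIFF."""
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    arr = np.clip(np.round(pixels * 65535.0), 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), arr)


def write_feature_table(rows: Iterable[tuple], path) -> None:
    """Write ``(image id, label, FeatureVector)`` rows as a CSV.

    Floats are stored with 12 significant digits so a read-back reproduces
    the values to that precision.  UTF-8, LF line endings.
    """
    records = []
    for row in rows:
        try:
            image_id, label, fv = row
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"malformed feature row {row!r}") from exc
        rec = {"id": image_id, "label": label}
        for name in FEATURE_COLUMNS:
            try:
                value = getattr(fv, name)
            except AttributeError:
                value = fv[name] if isinstance(fv, dict) and name in fv else None
            if value is None:
                raise ValidationError(f"row {image_id!r} is missing field {name!r}")
            rec[name] = value
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=("id", "label") + FEATURE_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature CSV back; validates the header."""
    df = pd.read_csv(path)
    expected = ("id", "label") + FEATURE_COLUMNS
    if tuple(df.columns) != expected:
        raise ValidationError(
            f"feature table header mismatch: got {tuple(df.columns)}"
        )
    return df
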