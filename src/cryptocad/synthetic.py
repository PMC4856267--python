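"""Synthetic endomicroscopy phantoms with ground truth.

Clinical confocal endomicroscopy frames of colorectal mucosa are not publicly
available, so this module generates stylized stand-ins that reproduce the two
morphologies the pipeline must tell apart:

* **normal** mucosa — dark, near-circular glandular crypts on a brighter
  stroma, sitting on a jittered hexagonal lattice at roughly equal spacing;
* **cancer** (adenocarcinoma) — disorganized tissue without round crypts:
  a band-pass random field smoothed anisotropically and warped by a smooth
  random displacement field, producing elongated, branching dark ridges.

Both classes receive a mild linear illumination gradient and multiplicative
speckle noise.  Every image is a pure function of its spec (including the
seed), so datasets are bit-reproducible.  The phantoms are a geometric
emulation, not a biophysical simulation: they carry the class-separating
structure (round features, edge sharpness) but none of the cellular detail
of real tissue.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .io import GrayImage, save_image

#: intensity plateaus of the noiseless construction
STROMA_LEVEL = 0.78
CRYPT_LEVEL = 0.30


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom image.

    Lengths are in pixels at the given ``side``.  ``lattice_spacing=None``
    defaults to 7/32 of the side (112 px at side 512), which yields on the
    order of 15-25 interior crypts — the magnitude seen in processed normal
    frames.  ``n_crypts`` pins the crypt count exactly (sites subsampled from
    the interior lattice).  ``distortion_amplitude`` (cancer only) is the RMS
    pixel displacement of the warp field; 0 degenerates toward periodic
    bands, which is allowed.
    """

    side: int = 512
    class_label: str = "normal"
    crypt_radius_mean: float = 14.0
    crypt_radius_sd: float = 2.0
    lattice_spacing: float | None = None
    lattice_jitter: float = 6.0
    n_crypts: int | None = None
    distortion_amplitude: float = 10.0
    noise_sd: float = 0.05
    illumination_gradient: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.side < 128:
            raise ParameterError("phantom side must be >= 128")
        if self.crypt_radius_mean <= 0:
            raise ParameterError("crypt radius must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def spacing(self) -> float:
        return self.lattice_spacing if self.lattice_spacing is not None else 0.21875 * self.side


def _circle_overlap_fraction(c1, r1, c2, r2) -> float:
    """Lens intersection area relative to the smaller circle's area."""
    d = float(np.hypot(c1[0] - c2[0], c1[1] - c2[1]))
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return 1.0
    a1 = r1**2 * np.arccos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * np.arccos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    a3 = 0.5 * np.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return float((a1 + a2 - a3) / (np.pi * min(r1, r2) ** 2))


def _finish(img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Shared post-processing: illumination ramp, speckle noise, clipping."""
    side = spec.side
    if spec.illumination_gradient != 0.0:
        angle = rng.uniform(0, 2 * np.pi)
        y, x = np.mgrid[0:side, 0:side]
        ramp = (np.cos(angle) * x + np.sin(angle) * y) / side
        img = img + spec.illumination_gradient * (ramp - ramp.mean())
    if spec.noise_sd > 0.0:
        img = img * (1.0 + rng.normal(0.0, spec.noise_sd, size=img.shape))
    return np.clip(img, 0.0, 1.0)


def generate_normal_phantom(spec: PhantomSpec) -> tuple[GrayImage, dict]:
    """Round dark crypts on a jittered hexagonal lattice over bright stroma.

    Crypt placements that would overlap a previous crypt by more than 20%
    of the smaller disk are resampled (up to 1000 attempts, then an error).
    Ground truth records each crypt's center and radius.
    """
    if spec.class_label != "normal":
        raise ParameterError("normal phantom requires class_label='normal'")
    rng = np.random.default_rng(spec.seed)
    side = spec.side
    a = spec.spacing
    margin = spec.crypt_radius_mean + 3 * spec.crypt_radius_sd + spec.lattice_jitter + 2

    # hexagonal lattice of candidate sites, interior only
    sites = []
    dy = a * np.sqrt(3) / 2
    row = 0
    y = margin
    while y <= side - margin:
        x0 = margin + (a / 2 if row % 2 else 0.0)
        x = x0
        while x <= side - margin:
            sites.append((x, y))
            x += a
        y += dy
        row += 1
    if spec.n_crypts is not None:
        if spec.n_crypts > len(sites):
            raise ParameterError(
                f"{spec.n_crypts} crypts requested but only {len(sites)} lattice sites fit"
            )
        chosen = rng.choice(len(sites), size=spec.n_crypts, replace=False)
        sites = [sites[i] for i in sorted(chosen)]

    centers, radii = [], []
    for sx, sy in sites:
        for _ in range(1000):
            cx = sx + rng.normal(0.0, spec.lattice_jitter)
            cy = sy + rng.normal(0.0, spec.lattice_jitter)
            r = max(3.0, rng.normal(spec.crypt_radius_mean, spec.crypt_radius_sd))
            ok = all(
                _circle_overlap_fraction((cx, cy), r, c, rr) <= 0.20
                for c, rr in zip(centers, radii)
            )
            if ok:
                centers.append((cx, cy))
                radii.append(r)
                break
        else:
            raise ParameterError("could not place a crypt without >20% overlap")

    img = np.full((side, side), STROMA_LEVEL)
    for (cx, cy), r in zip(centers, radii):
        x0, x1 = max(0, int(cx - r) - 1), min(side, int(cx + r) + 2)
        y0, y1 = max(0, int(cy - r) - 1), min(side, int(cy + r) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        img[y0:y1, x0:x1][inside] = CRYPT_LEVEL

    img = _finish(img, spec, rng)
    truth = {
        "class_label": "normal",
        "crypt_count": len(centers),
        "centers": [[float(c[0]), float(c[1])] for c in centers],
        "radii": [float(r) for r in radii],
    }
    return GrayImage(img, bit_depth=16), truth


def generate_tumor_phantom(spec: PhantomSpec) -> tuple[GrayImage, dict]:
    """Elongated dark ridges from a warped anisotropic random field."""
    if spec.class_label != "cancer":
        raise ParameterError("tumor phantom requires class_label='cancer'")
    rng = np.random.default_rng(spec.seed)
    side = spec.side
    scale = side / 512.0

    noise = rng.normal(size=(side, side))
    # directional smoothing -> elongated bands; orientation randomized by
    # sampling the axis-aligned field on a rotated (and warped) grid
    base = ndimage.gaussian_filter(noise, sigma=(2.5 * scale, 40.0 * scale), mode="wrap")
    angle = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    if spec.distortion_amplitude > 0:
        disp = []
        for _ in range(2):
            d = ndimage.gaussian_filter(rng.normal(size=(side, side)), 32.0 * scale, mode="wrap")
            d = d / max(d.std(), 1e-12) * spec.distortion_amplitude
            disp.append(d)
        yy = yy + disp[0]
        xx = xx + disp[1]
    c = (side - 1) / 2.0
    ca, sa = np.cos(angle), np.sin(angle)
    yr = c + ca * (yy - c) - sa * (xx - c)
    xr = c + sa * (yy - c) + ca * (xx - c)
    field = ndimage.map_coordinates(base, [yr, xr], order=1, mode="reflect")

    lo, hi = field.min(), field.max()
    f = (field - lo) / (hi - lo)
    # soft threshold at the median: dark elongated crypt-like bands with
    # blurred ("thickened") margins covering about half the field of view
    q = np.quantile(f, 0.5)
    ridge = 1.0 / (1.0 + np.exp((f - q) / 0.12))
    img = STROMA_LEVEL - (STROMA_LEVEL - CRYPT_LEVEL) * ridge

    img = _finish(img, spec, rng)
    truth = {
        "class_label": "cancer",
        "crypt_count": 0,
        "ridge_fraction": float(np.mean(ridge > 0.5)),
        "orientation_deg": float(angle),
    }
    return GrayImage(img, bit_depth=16), truth


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, dict]:
    if spec.class_label == "normal":
        return generate_normal_phantom(spec)
    if spec.class_label == "cancer":
        return generate_tumor_phantom(spec)
    raise ParameterError(f"unknown class label {spec.class_label!r}")


def sample_dataset(
    n_normal: int,
    n_cancer: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 42,
) -> Iterator[tuple[str, str, GrayImage, dict]]:
    """Yield ``(image id, label, image, truth)`` records.

    Per-image seeds are drawn once from a master generator, so the dataset is
    a pure function of (n_normal, n_cancer, base_spec, seed) and images can
    be streamed without holding the whole set in memory.
    """
    if n_normal < 0 or n_cancer < 0 or n_normal + n_cancer == 0:
        raise ParameterError("need at least one image")
    base = base_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_normal + n_cancer)
    k = 0
    for i in range(n_normal):
        spec = replace(base, class_label="normal", seed=int(child_seeds[k]))
        img, truth = generate_normal_phantom(spec)
        yield f"normal_{i:04d}", "normal", img, truth
        k += 1
    for i in range(n_cancer):
        spec = replace(base, class_label="cancer", seed=int(child_seeds[k]))
        img, truth = generate_tumor_phantom(spec)
        yield f"cancer_{i:04d}", "cancer", img, truth
        k += 1


def generate_dataset(
    n_normal: int,
    n_cancer: int,
    out_dir,
    base_spec: PhantomSpec | None = None,
    seed: int = 42,
) -> dict:
    """Write a labeled phantom dataset: PNGs, ``labels.csv``, ``truth.json``.

    Returns a manifest with per-file SHA-256 hashes (dataset fingerprint).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["id,label,filename"]
    truths = {}
    hashes = {}
    for image_id, label, img, truth in sample_dataset(n_normal, n_cancer, base_spec, seed):
        fname = f"{image_id}.png"
        save_image(img, out / fname)
        rows.append(f"{image_id},{label},{fname}")
        truths[image_id] = truth
        hashes[fname] = hashlib.sha256((out / fname).read_bytes()).hexdigest()
    (out / "labels.csv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    (out / "truth.json").write_text(json.dumps(truths, indent=1, sort_keys=True), encoding="utf-8")
    manifest = {"n_normal": n_normal, "n_cancer": n_cancer, "seed": seed, "files": hashes}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return manifest
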