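# Methods

This note documents the models, conventions and design choices behind
`cryptocad`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Image model and coordinate frame

Images are single-channel, held as unit-interval float64 regardless of source
bit depth (8- or 16-bit PNG/TIFF), so every downstream operation has one code
path. The frame is row-major, origin top-left, pixel centers at integer
coordinates with x = column and y = row; contour vertices use this frame.
Color inputs are rejected unless luminance conversion (ITU-R 601) is
explicitly requested — CLE frames are single-channel, so a color file usually
signals a handling error, and silent conversion would hide it.

## Binarization

Both the fractal and the crypt-feature modules operate on a thresholded
version of the Gaussian-smoothed image. The default threshold is Otsu's
criterion over a 256-bin histogram (foreground = intensity strictly above
threshold); a fixed threshold `fixed:<t>` is available. Constant images are
rejected rather than given a sentinel value: they are invalid pipeline inputs
and silently propagating them would poison group statistics. One threshold
pass is shared by the fractal and feature modules (they describe the same
pattern; decoupled settings remain possible through the module APIs).

## Gaussian smoothing

The smoothing kernel is separable and built from *integrated* Gaussians: the
weight at offset k is the Gaussian probability mass on [k−½, k+½] (an erf
difference), truncated at radius 6σ and renormalized. Unlike a point-sampled
kernel, this reproduces the continuous error-function profile of a smoothed
step edge to ~1e−9, which keeps sub-pixel contour placement unbiased.
Boundaries are reflective, so a constant image is a fixed point and total
intensity is conserved. The default width is σ = 2 px at the 1024×1024
acquisition scale, rescaled proportionally to the image side (σ = 1 px at
512); endomicroscopy speckle is near pixel-scale, so a width of a couple of
pixels suppresses it without erasing crypt boundaries.

## Fractal dimension

Box counting uses a top-left-anchored grid; partial boxes along the right and
bottom edges are counted, so no pixel margin is discarded (and the oracle
tests enumerate the same grid). Default scales are dyadic, 2 to side/4 —
at least three scales are required for a meaningful fit. The dimension is the
unweighted least-squares slope of log N(s) against log(1/s); the fit R² is
reported. For any 2-D mask consecutive dyadic slopes lie in [0, 2], so the
fitted dimension does as well. A scale with zero count cannot occur for a
nonempty mask; empty masks are rejected.

## Lacunarity

The gliding box visits all (H−r+1)(W−r+1) positions (window sums via an
integral image, exact in int64). The reported scalar is the mean over
r ∈ {2, 4, 8, 16} of Λ(r) − 1 = M₂/M₁² − 1. The −1 normalization makes a
translation-invariant pattern score exactly 0 and matches the near-zero
magnitudes typical of published mucosa values; it is configurable.

## GLCM texture statistics

Intensities are quantized into 8 equal-width bins spanning the per-image
[min, max] (exposure-invariant; a fixed [0, 1] range is available), and
co-occurrences are counted at a single offset (0, 1) without symmetrization —
the classic toolbox defaults when a single scalar per statistic is reported
per image. Homogeneity uses the 1/(1+|i−j|) form. Note that some libraries
(including scikit-image) use 1/(1+(i−j)²) for "homogeneity"; the test suite
cross-checks contrast/correlation/energy against scikit-image and homogeneity
against a brute-force oracle for this reason. Correlation is undefined when a
marginal variance vanishes (constant image); this raises.

## Crypt-feature detection and roundness

Isocontours are extracted by marching squares with linear interpolation
(scikit-image's `find_contours`). Contours are traced on the *smoothed
grayscale* at the binarization threshold — the same level set as the binary
mask's boundary, but with sub-pixel crossings. Tracing the 0/1 mask instead
quantizes crossings to edge midpoints, which biases measured disk perimeters
upward by about 6%; sub-pixel tracing brings disk area and perimeter within
3% of the analytic circle at radius 20. Saddle cells are resolved by the
library's documented connectivity rule, so results are deterministic.

Closed contours are scored by the roundness ratio area/perimeter in pixels
(shoelace area, Euclidean perimeter with the closing edge). The ratio is
≈ r/2 for a disk of radius r and ≈ half the width for a thin strip, so a
cutoff of 4 px separates round crypts (radius ≳ 8 px at acquisition scale)
from elongated fragments. Because the ratio carries pixel units, the cutoff
is expressed at the 1024×1024 reference scale and rescaled by side/1024 by
default (`features.rescale_threshold`), so the same physical geometry is
counted at any resolution. Contours touching the image border are excluded:
their geometry is truncated by the field of view and the ratio would be
meaningless. An alternative dimensionless roundness (4πA/P²) was considered
and rejected: the pixel-unit ratio is the convention the cutoff value 4 was
defined for.

## Decision module

A two-layer feed-forward network: 7 inputs standardized by the *training
split's* mean and sd (a constant feature gets sd 1 — it carries no signal
either way), 100 logistic-sigmoid hidden units (tanh available), 2 softmax
outputs, mean natural-log cross-entropy loss with one-hot targets. Training
is full-batch Adam (rate 0.01), at most 1000 epochs, stopping when the
validation loss has not improved for 6 consecutive epochs and restoring the
best-validation weights. Everything is seeded: weight initialization, the
split shuffle, phantom generation — two runs with the same inputs are
bit-identical, and permuting rows inside the validation or test split cannot
change the trained model (no leakage; the validation set enters only through
its permutation-invariant mean loss). Cross-entropy is reported *per sample*
(natural log); published tables do not always state their convention, so this
one is fixed here for comparability. Probability ties classify as "cancer" —
the conservative direction for a screening aid. Classes are unweighted; with
a roughly 1:2 normal:cancer mix nothing in the data motivates reweighting.

The three-way split uses largest-remainder rounding (floors plus residual
units by descending fractional remainder, ties to the earlier of
train/validation/test), which maps 1035 images at 70/15/15 to exactly
725/155/155. Splitting is by image, not by patient; with multiple images per
patient this leaks patient identity across splits and makes error estimates
optimistic — a documented limitation of the protocol being reproduced, not of
the implementation.

## Phantom generator

The generator emulates the two morphologies at 512×512 by default (same
geometry as 1024 at a quarter of the cost, with the roundness cutoff rescaled
accordingly):

* **Normal**: dark disks (intensity 0.30) on bright stroma (0.78), radii
  ~N(14, 2²) px, centers on a hexagonal lattice (spacing 7/32 of the side
  ≈ 112 px) with N(0, 6²) jitter; placements overlapping a previous crypt by
  more than 20% (exact lens-area criterion) are resampled. With no noise and
  no gradient the construction has exactly two intensity plateaus; edge
  softness comes from the pipeline's own smoothing, as in real optics.
  Defaults give on the order of 20 interior crypts per frame — the magnitude
  reported for processed normal frames.
* **Cancer**: white noise smoothed anisotropically (σ = 2.5/40 px) to form
  elongated bands at a random orientation, warped by a smooth random
  displacement field (RMS 10 px, correlation length 32 px), then
  soft-thresholded at the median (logistic margin 0.12 of the range) into
  dark, branching, border-spanning ridges. Round closed structures are rare
  by construction; the soft margins lower GLCM contrast relative to the
  hard-edged crypts. Zero distortion degenerates toward periodic bands —
  allowed, and useful as a limiting case.

Both classes get a random-direction linear illumination ramp (amplitude 0.08)
and multiplicative speckle (sd 0.05), then clipping to [0, 1]. Every image is
a pure function of its spec; dataset seeds are spawned from one master seed.

What the phantoms deliberately do **not** emulate: goblet cells, vasculature,
fluorescein leakage, motion artifacts, patient-level correlation, and the
full variability of tissue. Consequently the phantom benchmark (held-out
error ~0% at default settings) demonstrates that the pipeline extracts and
uses the discriminating structure correctly — it does not estimate clinical
accuracy, which on real tissue is far worse than on phantoms.

## Group statistics

Per-parameter two-sample, two-tailed t-tests; Welch's unequal-variance form
by default (pooled available for comparability with spreadsheet defaults),
α = 0.05, no multiple-testing correction (per-parameter reporting).
Degenerate cases follow fixed conventions: both groups constant and equal →
p = 1; both constant and unequal → p = 0 with a warning. Images are treated
as independent samples; see the split-leakage caveat above.

## Problem sizes used in tests

Oracle-equivalence tests run on small grids (16×16 GLCMs, 32×32 lacunarity
masks, 64×64 box counts) where exhaustive enumeration is exact and fast. The
end-to-end benchmark uses the full 1035-image phantom set at side 512; the
CLI round-trip checks use 16-image sets at sides 160–192, enough to exercise
every code path while keeping the default suite around three minutes.
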