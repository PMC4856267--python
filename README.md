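# cryptocad

Quantitative analysis of confocal laser endomicroscopy (CLE) images of
colorectal mucosa, for gastroenterologists and imaging researchers who want an
objective, reproducible alternative to visual pattern reading.

In CLE frames, healthy colonic mucosa shows round glandular crypts at roughly
equal spacing; adenocarcinoma shows disorganized tissue with elongated,
interrupted crypts. `cryptocad` turns each grayscale frame into seven
dimensionless parameters and feeds them to a small neural network that labels
the image *normal* or *cancer*:

1. **Fractal dimension** — box-counting slope
   D = slope of log N(s) versus log(1/s), where N(s) is the number of s×s
   grid boxes occupied by the binarized pattern.
2. **Lacunarity** — gliding-box statistic; with M₁, M₂ the first two moments
   of the r×r window mass, Λ(r) = M₂/M₁² and the reported value is the mean
   of Λ(r) − 1 over r ∈ {2, 4, 8, 16} (0 for translation-invariant mass,
   larger for gappier patterns).
3–6. **GLCM texture statistics** on the grey-level co-occurrence matrix
   P(i, j) (8 levels, offset (0, 1)):
   contrast Σ(i−j)²P, correlation Σ(i−μᵢ)(j−μⱼ)P/(σᵢσⱼ),
   energy ΣP², homogeneity ΣP/(1+|i−j|).
7. **Feature count** — the image is Gaussian-smoothed, thresholded (Otsu),
   isocontours are traced by marching squares with linear interpolation, and
   each closed contour is scored by the roundness ratio area/perimeter
   (≈ r/2 for a disk of radius r). Contours scoring above 4 px (at the
   1024×1024 reference scale) are counted as round crypts.

The decision module is a two-layer feed-forward network — 100 logistic-sigmoid
hidden units, 2-unit softmax output — trained on the standardized
seven-parameter vectors by full-batch Adam with early stopping on a validation
split (mean natural-log cross-entropy loss). A Welch t-test module summarizes
the per-parameter group differences.

Because clinical CLE images are rarely shareable, the package ships a phantom
generator that emulates both morphologies with exact ground truth, so the
whole pipeline is testable end to end.

## Worked example

```python
from cryptocad import (PhantomSpec, extract_feature_vector,
                       generate_normal_phantom, generate_tumor_phantom)

img, truth = generate_normal_phantom(PhantomSpec(seed=1))
print(truth["crypt_count"], extract_feature_vector(img))

img, _ = generate_tumor_phantom(PhantomSpec(class_label="cancer", seed=1))
print(extract_feature_vector(img))
```

prints (seed 1, 512×512 phantoms):

```
normal  (23 crypts drawn):
  fractal_dimension = 1.987   lacunarity = 0.0475
  contrast = 0.5834  correlation = 0.8142  energy = 0.2445  homogeneity = 0.7861
  feature_count = 23
cancer:
  fractal_dimension = 1.856   lacunarity = 0.6563
  contrast = 0.3858  correlation = 0.9085  energy = 0.0903  homogeneity = 0.8183
  feature_count = 7
```

The detector recovers all 23 round crypts of the normal phantom; the tumor
phantom's elongated ridges yield few round features and visibly lower GLCM
contrast — the two directions that separate the classes.

The same workflow from the shell:

```sh
cryptocad simulate --n-normal 356 --n-cancer 679 --side 512 --seed 42 --out imgs/
cryptocad extract  --in imgs/ --labels imgs/labels.csv --out features.csv
cryptocad train    --features features.csv --out model.json --seed 42
cryptocad report   --features features.csv --out table.csv
```

`train` prints the per-split cross-entropy and decision-accuracy error (the
percent of misclassified images); `report` writes the per-parameter
mean ± sd, t statistic, p value and significance flag for normal vs. cancer.

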