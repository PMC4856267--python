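"""End-to-end surrogate benchmark on phantom data.

Runs the whole pipeline the way the original study ran it on clinical
frames: generate a labeled image set (356 normal + 679 cancer by default),
extract the seven parameters per image, split 725/155/155, train the
100-hidden-unit network with early stopping, and report cross-entropy and
decision-accuracy error per split.  Phantoms are far cleaner than clinical
tissue, so the errors here bound what the method achieves on ideal input —
they are not clinical performance estimates.
"""

from __future__ import annotations

import numpy as np

from .classify import TrainConfig, split_dataset, train
from .config import PipelineConfig
from .pipeline import extract_feature_vector
from .stats import compare_groups
from .synthetic import PhantomSpec, sample_dataset


def extract_dataset_features(
    n_normal: int,
    n_cancer: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 42,
    config: PipelineConfig | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Stream phantoms through the extractor; return (matrix, labels, ids)."""
    cfg = config or PipelineConfig()
    X, labels, ids = [], [], []
    for image_id, label, img, _truth in sample_dataset(n_normal, n_cancer, base_spec, seed):
        fv = extract_feature_vector(img, cfg, image_id=image_id)
        X.append(fv.to_array())
        labels.append(label)
        ids.append(image_id)
    return np.stack(X), labels, ids


def run_surrogate_benchmark(
    seed: int = 42,
    n_normal: int = 356,
    n_cancer: int = 679,
    side: int = 512,
    config: PipelineConfig | None = None,
    hyper: TrainConfig | None = None,
) -> dict:
    """Full pipeline on phantoms; returns per-split metrics and group stats."""
    spec = PhantomSpec(side=side)
    X, labels, ids = extract_dataset_features(n_normal, n_cancer, spec, seed, config)
    split = split_dataset(len(labels), (0.70, 0.15, 0.15), seed=seed)
    model, report = train(X, labels, split, hyper or TrainConfig(), seed=seed)
    comparison = compare_groups(
        X[[l == "normal" for l in labels]], X[[l == "cancer" for l in labels]]
    )
    return {
        "n_images": len(labels),
        "split_sizes": [len(split.train), len(split.validation), len(split.test)],
        "cross_entropy": report.cross_entropy,
        "decision_accuracy_error": report.decision_accuracy_error,
        "confusion": report.confusion,
        "epochs_run": len(model.training_log),
        "group_comparison": comparison.to_frame().to_dict(orient="records"),
    }
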