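"""Two-layer feed-forward neural classifier (normal vs. cancer).

A classic pattern-recognition network: 7 standardized inputs, one hidden
layer of 100 logistic-sigmoid units, a 2-unit softmax output, trained by
full-batch Adam on the mean natural-log cross-entropy with early stopping on
a held-out validation split (training stops once the validation loss has
failed to improve for ``patience`` consecutive epochs, and the weights from
the best-validation epoch are returned).

Standardization statistics (mean, sd) are estimated on the TRAINING split
only, so validation and test data never leak into the model.  Given the same
data, hyperparameters and seed, training is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, TrainingError, ValidationError

#: output-unit order; index 1 ("cancer") wins probability ties (conservative)
CLASSES = ("normal", "cancer")


@dataclass
class SplitIndices:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


@dataclass
class TrainConfig:
    hidden_units: int = 100
    activation: str = "logistic"  # or "tanh"
    learning_rate: float = 0.01
    max_epochs: int = 1000
    patience: int = 6


@dataclass
class MLPModel:
    W1: np.ndarray  # (hidden, n_features)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (2, hidden)
    b2: np.ndarray  # (2,)
    input_mean: np.ndarray  # (n_features,)
    input_sd: np.ndarray  # (n_features,)
    activation: str = "logistic"
    seed: int | None = None
    training_log: list = field(default_factory=list)  # (epoch, train loss, val loss)


@dataclass
class EvalReport:
    """Cross-entropy, percent misclassified and confusion counts per split."""

    cross_entropy: dict
    decision_accuracy_error: dict  # percent in [0, 100]
    confusion: dict  # split -> 2x2 list, rows = true class, cols = predicted


def split_dataset(n: int, proportions=(0.70, 0.15, 0.15), seed: int = 0) -> SplitIndices:
    """Random three-way split with largest-remainder size rounding.

    Sizes are floor(n * p) plus one unit per largest fractional remainder
    until n is reached; remainder ties go to the earlier split (train,
    validation, test order).  Assignment is a seeded shuffle.
    """
    if n < 3:
        raise ParameterError("need at least 3 samples to split")
    p = np.asarray(proportions, dtype=np.float64)
    if len(p) != 3 or np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ParameterError("proportions must be 3 positive numbers summing to 1")
    exact = n * p
    sizes = np.floor(exact).astype(int)
    remainders = exact - sizes
    # stable sort: descending remainder, ties broken by split order
    order = sorted(range(3), key=lambda k: (-remainders[k], k))
    for k in order[: n - sizes.sum()]:
        sizes[k] += 1
    perm = np.random.default_rng(seed).permutation(n)
    t, v = sizes[0], sizes[0] + sizes[1]
    return SplitIndices(train=perm[:t], validation=perm[t:v], test=perm[v:])


def _one_hot(labels) -> np.ndarray:
    idx = np.array([CLASSES.index(l) for l in labels])
    out = np.zeros((len(idx), 2))
    out[np.arange(len(idx)), idx] = 1.0
    return out


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-z))
    if kind == "tanh":
        return np.tanh(z)
    raise ParameterError(f"unknown activation {kind!r}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities for raw (unstandardized) inputs."""
    Xs = (X - model.input_mean) / model.input_sd
    H = _activate(Xs @ model.W1.T + model.b1, model.activation)
    return _softmax(H @ model.W2.T + model.b2)


def _cross_entropy(P: np.ndarray, Y: np.ndarray) -> float:
    return float(-np.mean(np.log(np.clip(np.sum(P * Y, axis=1), 1e-300, None))))


def train(
    features: np.ndarray,
    labels,
    split: SplitIndices,
    hyper: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[MLPModel, EvalReport]:
    """Train the network and report all three splits at the selected epoch.

    ``features`` is (n, 7) raw feature vectors; ``labels`` a sequence of
    "normal"/"cancer".  Raises if the training split contains fewer than two
    examples of either class or if the loss diverges.
    """
    cfg = hyper or TrainConfig()
    X = np.asarray(features, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite feature values")
    Y = _one_hot(labels)
    tr, va = split.train, split.validation
    counts = Y[tr].sum(axis=0)
    if np.any(counts < 2):
        raise TrainingError(
            f"training split needs >= 2 examples per class, got {counts.astype(int).tolist()}"
        )
    mean = X[tr].mean(axis=0)
    sd = X[tr].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant features carry no signal

    rng = np.random.default_rng(seed)
    n_in = X.shape[1]
    h = cfg.hidden_units
    W1 = rng.normal(0.0, np.sqrt(1.0 / n_in), size=(h, n_in))
    b1 = np.zeros(h)
    W2 = rng.normal(0.0, np.sqrt(1.0 / h), size=(2, h))
    b2 = np.zeros(2)

    model = MLPModel(W1, b1, W2, b2, mean, sd, cfg.activation, seed)
    Xtr, Ytr = X[tr], Y[tr]
    Xva, Yva = X[va], Y[va]

    # Adam state
    params = [W1, b1, W2, b2]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    Xs = (Xtr - mean) / sd
    best = (np.inf, -1, None)  # val loss, epoch, weights
    stall = 0
    for epoch in range(1, cfg.max_epochs + 1):
        Hlin = Xs @ W1.T + b1
        H = _activate(Hlin, cfg.activation)
        P = _softmax(H @ W2.T + b2)
        train_loss = _cross_entropy(P, Ytr)
        if not np.isfinite(train_loss):
            raise TrainingError(f"loss diverged at epoch {epoch}")

        # backprop, mean-CE gradients
        n = len(Xs)
        dZ2 = (P - Ytr) / n  # (n, 2)
        gW2 = dZ2.T @ H
        gb2 = dZ2.sum(axis=0)
        dH = dZ2 @ W2
        if cfg.activation == "logistic":
            dZ1 = dH * H * (1.0 - H)
        else:
            dZ1 = dH * (1.0 - H**2)
        gW1 = dZ1.T @ Xs
        gb1 = dZ1.sum(axis=0)

        for p, g, mm, vv in zip(params, [gW1, gb1, gW2, gb2], m_t, v_t):
            mm *= beta1
            mm += (1 - beta1) * g
            vv *= beta2
            vv += (1 - beta2) * g**2
            mhat = mm / (1 - beta1**epoch)
            vhat = vv / (1 - beta2**epoch)
            p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

        val_loss = _cross_entropy(_forward(model, Xva), Yva)
        model.training_log.append((epoch, train_loss, val_loss))
        if val_loss < best[0]:
            best = (val_loss, epoch, [p.copy() for p in params])
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    if best[2] is not None:
        model.W1, model.b1, model.W2, model.b2 = best[2]
    report = evaluate(model, X, labels, split)
    return model, report


def classify(model: MLPModel, fv) -> tuple[str, np.ndarray]:
    """Label one feature vector; ties resolve to "cancer"."""
    arr = fv.to_array() if hasattr(fv, "to_array") else np.asarray(fv, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("feature vector contains non-finite values")
    probs = _forward(model, arr[None, :])[0]
    label = CLASSES[1] if probs[1] >= probs[0] else CLASSES[0]
    return label, probs


def predict_proba(model: MLPModel, features: np.ndarray) -> np.ndarray:
    return _forward(model, np.asarray(features, dtype=np.float64))


def evaluate(model: MLPModel, features, labels, split: SplitIndices) -> EvalReport:
    """Mean cross-entropy and percent misclassified per split."""
    X = np.asarray(features, dtype=np.float64)
    Y = _one_hot(labels)
    ce, err, conf = {}, {}, {}
    for name, idx in (("training", split.train), ("validation", split.validation), ("test", split.test)):
        if len(idx) == 0:
            raise ParameterError(f"{name} split is empty")
        P = _forward(model, X[idx])
        ce[name] = _cross_entropy(P, Y[idx])
        pred = np.where(P[:, 1] >= P[:, 0], 1, 0)
        true = Y[idx].argmax(axis=1)
        err[name] = 100.0 * float(np.mean(pred != true))
        c = np.zeros((2, 2), dtype=int)
        np.add.at(c, (true, pred), 1)
        conf[name] = c.tolist()
    return EvalReport(cross_entropy=ce, decision_accuracy_error=err, confusion=conf)


def save_model(model: MLPModel, path) -> None:
    """Serialize to JSON: plain nested arrays plus the training seed."""
    payload = {
        "format": "cryptocad-mlp-v1",
        "classes": list(CLASSES),
        "activation": model.activation,
        "seed": model.seed,
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": model.b2.tolist(),
        "input_mean": model.input_mean.tolist(),
        "input_sd": model.input_sd.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_model(path) -> MLPModel:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    if d.get("format") != "cryptocad-mlp-v1":
        raise ValidationError(f"{path}: not a cryptocad model file")
    return MLPModel(
        W1=np.array(d["W1"]),
        b1=np.array(d["b1"]),
        W2=np.array(d["W2"]),
        b2=np.array(d["b2"]),
        input_mean=np.array(d["input_mean"]),
        input_sd=np.array(d["input_sd"]),
        activation=d["activation"],
        seed=d["seed"],
    )
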