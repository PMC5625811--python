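"""Linear maximum-margin classifiers for the EEG channel.

Two classifiers operate on the same eight-band power features: a four-class
emotion-state classifier and a three-class emotion-intensity classifier.
Both are one-vs-rest linear SVMs; the per-class decision values
``w_k . x + b_k`` are the channel's raw scores, which downstream code
min-max normalizes and fuses.

Features are z-scored with training-set statistics before the margin fit;
the scaler is part of the serialized model. The fit itself is delegated to
scikit-learn's deterministic liblinear primal solver, and the learned
weights are extracted into a plain, JSON-serializable :class:`LinearModel`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .labels import (
    EmotionState,
    IntensityLevel,
    STATE_ORDER,
    INTENSITY_ORDER,
    intensity_from_index,
)

__all__ = [
    "LinearModel",
    "train_state_model",
    "train_intensity_model",
    "score_states",
    "score_intensity",
    "classify_state",
    "classify_intensity",
]

N_FEATURES = 8


@dataclass
class LinearModel:
    """One-vs-rest linear classifier with a built-in feature scaler.

    ``weights`` has one row per class in canonical label order; the decision
    value for class k on input x is ``weights[k] . z + biases[k]`` where
    ``z = (x - scaler_mean) / scaler_scale``.
    """

    weights: np.ndarray  # (n_classes, 8)
    biases: np.ndarray  # (n_classes,)
    scaler_mean: np.ndarray  # (8,)
    scaler_scale: np.ndarray  # (8,)
    classes: tuple[int, ...]  # label codes, canonical order

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[1] != self.weights.shape[1]:
            raise ValueError(
                f"feature dimension {x.shape[1]} does not match model ({self.weights.shape[1]})"
            )
        z = (x - self.scaler_mean) / self.scaler_scale
        d = z @ self.weights.T + self.biases
        return d[0] if squeeze else d

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "classes": list(self.classes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            biases=np.asarray(d["biases"], dtype=float),
            scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
            scaler_scale=np.asarray(d["scaler_scale"], dtype=float),
            classes=tuple(int(c) for c in d["classes"]),
        )

    def save(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: "str | Path") -> "LinearModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _fit_linear(
    features: np.ndarray,
    codes: np.ndarray,
    canonical: Sequence[int],
    regularization: float,
) -> LinearModel:
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        X = X.reshape(len(codes), -1)
    if X.shape[0] != codes.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows but {codes.shape[0]} labels")
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features per sample, got {X.shape[1]}")
    if regularization <= 0:
        raise ValueError("regularization weight must be positive")
    present = sorted(set(codes.tolist()))
    if len(present) < 2:
        raise ValueError("training data contains a single class; need at least 2")
    unknown = set(present) - set(canonical)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} outside the class set {list(canonical)}")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0  # constant features pass through unscaled
    Z = (X - mean) / scale

    # Primal liblinear is deterministic; random_state pinned for belt and braces.
    svc = LinearSVC(C=regularization, dual=False, random_state=0)
    svc.fit(Z, codes)

    n = len(canonical)
    W = np.zeros((n, N_FEATURES))
    b = np.zeros(n)
    if len(present) == 2:
        # sklearn collapses binary to a single signed decision function
        # oriented toward classes_[1]; expand to two opposite rows.
        w = svc.coef_[0]
        lo, hi = svc.classes_
        idx = {int(c): i for i, c in enumerate(canonical)}
        W[idx[int(hi)]], b[idx[int(hi)]] = w, svc.intercept_[0]
        W[idx[int(lo)]], b[idx[int(lo)]] = -w, -svc.intercept_[0]
        # classes absent from training keep zero rows: they score 0 and
        # never dominate a confident decision.
    else:
        idx_model = {int(c): i for i, c in enumerate(svc.classes_)}
        for i, c in enumerate(canonical):
            if c in idx_model:
                W[i] = svc.coef_[idx_model[c]]
                b[i] = svc.intercept_[idx_model[c]]
            # classes absent from training keep zero rows
    return LinearModel(
        weights=W, biases=b, scaler_mean=mean, scaler_scale=scale, classes=tuple(canonical)
    )


def train_state_model(
    features: Iterable[Sequence[float]],
    labels: Iterable[EmotionState],
    regularization: float = 1.0,
) -> LinearModel:
    """Fit the four-class emotion-state classifier on band-power features."""
    codes = np.asarray([int(EmotionState(l)) for l in labels])
    X = np.asarray(list(features), dtype=float)
    return _fit_linear(X, codes, [int(s) for s in STATE_ORDER], regularization)


def train_intensity_model(
    features: Iterable[Sequence[float]],
    labels: Iterable[IntensityLevel],
    regularization: float = 1.0,
) -> LinearModel:
    """Fit the three-class emotion-intensity classifier on band-power features."""
    codes = np.asarray([int(IntensityLevel(l)) for l in labels])
    X = np.asarray(list(features), dtype=float)
    return _fit_linear(X, codes, [int(v) for v in INTENSITY_ORDER], regularization)


def _require_classes(model: LinearModel, canonical: Sequence[int], kind: str) -> None:
    if tuple(model.classes) != tuple(canonical):
        raise ValueError(
            f"model classes {model.classes} are not the {kind} class set {tuple(canonical)}"
        )


def score_states(model: LinearModel, x: np.ndarray) -> np.ndarray:
    """Raw 4-score vector s2 (decision values) in canonical state order."""
    _require_classes(model, [int(s) for s in STATE_ORDER], "emotion-state")
    return model.decision_values(np.asarray(x, dtype=float))


def score_intensity(model: LinearModel, x: np.ndarray) -> np.ndarray:
    """Raw 3-score vector s2' in (weak, moderate, strong) order."""
    _require_classes(model, [int(v) for v in INTENSITY_ORDER], "emotion-intensity")
    return model.decision_values(np.asarray(x, dtype=float))


def classify_state(model: LinearModel, x: np.ndarray) -> EmotionState:
    """r2: state of the maximal decision value; ties to the lower code."""
    return STATE_ORDER[int(np.argmax(score_states(model, x)))]


def classify_intensity(model: LinearModel, x: np.ndarray) -> IntensityLevel:
    """r2': intensity of the maximal decision value; ties to weak < moderate < strong."""
    return intensity_from_index(int(np.argmax(score_intensity(model, x))))
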