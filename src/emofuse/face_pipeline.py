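"""Facial-expression channel: crop -> PCA -> one-hidden-layer network.

The face branch localizes a face in a grayscale frame, resizes the crop to
48 x 48 with intensities in [0, 1], projects the flattened image onto the
top-D principal components of the training set, and scores the four emotion
states with a feedforward network (D inputs, one hidden layer of N logistic
units, 4 logistic outputs) trained by per-sample stochastic gradient
descent on a squared-error loss against one-hot targets.

Hyperparameters (D, N, R) are selected by exhaustive grid search over

    D in {121, 144, 169, 225},  N in {150, 200, 250, 300},
    R in {0.001, 0.01, 0.1, 1}

maximizing validation accuracy; the shipped default is (169, 200, 0.1).

Face *detection* is a pluggable stage: any callable mapping a grayscale
array to a bounding box (or ``None``) can be used; a brightest-blob stub is
bundled for synthetic frames, and an adapter to a pretrained frontal-face
cascade can be supplied by the user. PCA and the network are implemented
here directly — both are small, and the explicit weights keep models
JSON-serializable and training bit-reproducible under a seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .labels import EmotionState, STATE_ORDER
from . import fusion

__all__ = [
    "FACE_SIZE",
    "crop_face",
    "brightest_blob_detector",
    "to_grayscale",
    "PCAModel",
    "fit_pca",
    "project",
    "HyperParams",
    "DEFAULT_GRID",
    "NNModel",
    "train_nn",
    "score_faces",
    "FaceScores",
    "grid_search",
    "GridSearchResult",
]

FACE_SIZE = 48  # pixels per side after cropping
N_PIXELS = FACE_SIZE * FACE_SIZE

#: Bounding box as (row_start, row_stop, col_start, col_stop), stop-exclusive.
BoundingBox = tuple[int, int, int, int]
Detector = Callable[[np.ndarray], "BoundingBox | None"]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) color image by the Rec. 601 luma transform."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        if image.shape[2] == 1:
            return image[:, :, 0]
        r, g, b = image[:, :, 0], image[:, :, 1], image[:, :, 2]
        return 0.299 * r + 0.587 * g + 0.114 * b
    return image


def brightest_blob_detector(gray: np.ndarray) -> "BoundingBox | None":
    """Detector stub: bounding box of above-midrange pixels.

    Intended for synthetic frames where the face is the bright region on a
    dark canvas; returns ``None`` when the frame is flat.
    """
    lo, hi = float(gray.min()), float(gray.max())
    if hi <= lo:
        return None
    mask = gray > (lo + hi) / 2.0
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def crop_face(image: np.ndarray, detector: "Detector | None" = None) -> np.ndarray:
    """Localize, crop and normalize a face frame to 48 x 48 in [0, 1].

    If ``detector`` returns a box, that region is cropped; otherwise (or if
    no detector is given) the whole frame is used. The crop is resized
    bilinearly to 48 x 48. 8-bit inputs (max > 1) are divided by 255.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    gray = to_grayscale(image)
    if gray.max() > 1.0:
        gray = gray / 255.0
    if detector is not None:
        box = detector(gray)
        if box is not None:
            r0, r1, c0, c1 = box
            gray = gray[r0:r1, c0:c1]
            if gray.size == 0:
                raise ValueError(f"detector returned an empty box {box}")
    if gray.shape != (FACE_SIZE, FACE_SIZE):
        gray = _sk_resize(gray, (FACE_SIZE, FACE_SIZE), order=1, anti_aliasing=False)
    return np.clip(gray, 0.0, 1.0)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Mean image + top-D orthonormal components (rows of ``basis``)."""

    mean: np.ndarray  # (2304,)
    basis: np.ndarray  # (D, 2304), rows orthonormal
    D: int

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "basis": self.basis.tolist(), "D": self.D}

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(np.asarray(d["mean"], float), np.asarray(d["basis"], float), int(d["D"]))


def _flatten_images(images: Sequence[np.ndarray]) -> np.ndarray:
    X = np.stack([np.asarray(im, dtype=float).reshape(-1) for im in images])
    if X.shape[1] != N_PIXELS:
        raise ValueError(f"images must be {FACE_SIZE}x{FACE_SIZE}; got {X.shape[1]} pixels")
    return X


def fit_pca(images: Sequence[np.ndarray], D: int) -> PCAModel:
    """Top-D principal components of the training images.

    Deterministic: components come from the SVD of the centered data matrix,
    with each component's sign fixed so its largest-magnitude coordinate is
    positive. Raises if ``D`` exceeds the number of images, the pixel count,
    or the rank of the centered data (zero-variance directions carry no
    information to project onto).
    """
    X = _flatten_images(images)
    n = X.shape[0]
    if D < 1:
        raise ValueError("D must be >= 1")
    if D > n:
        raise ValueError(f"D={D} exceeds the number of training images ({n})")
    if D > N_PIXELS:
        raise ValueError(f"D={D} exceeds the pixel count ({N_PIXELS})")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > max(n, N_PIXELS) * np.finfo(float).eps * (s[0] if s.size else 0.0)))
    if rank < D:
        raise ValueError(
            f"training data has rank {rank} < D={D} (zero-variance components)"
        )
    basis = Vt[:D].copy()
    for row in basis:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(mean=mean, basis=basis, D=D)


def project(pca: PCAModel, img: np.ndarray) -> np.ndarray:
    """Project a 48 x 48 image onto the PCA basis: basis @ (flat - mean)."""
    if pca.basis is None or pca.basis.size == 0:
        raise ValueError("PCA model is not fitted")
    flat = np.asarray(img, dtype=float).reshape(-1)
    if flat.size != pca.mean.size:
        raise ValueError(f"image has {flat.size} pixels, model expects {pca.mean.size}")
    return pca.basis @ (flat - pca.mean)


# ---------------------------------------------------------------------------
# Feedforward network
# ---------------------------------------------------------------------------

DEFAULT_GRID: dict[str, tuple] = {
    "D": (121, 144, 169, 225),
    "N": (150, 200, 250, 300),
    "R": (0.001, 0.01, 0.1, 1.0),
}


@dataclass(frozen=True, order=True)
class HyperParams:
    """Face-branch hyperparameters: PCA dim D, hidden units N, learning rate R."""

    D: int = 169
    N: int = 200
    R: float = 0.1


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class NNModel:
    """One-hidden-layer network with logistic hidden and output units."""

    W1: np.ndarray  # (N, D)
    b1: np.ndarray  # (N,)
    W2: np.ndarray  # (4, N)
    b2: np.ndarray  # (4,)
    learning_rate: float

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Output activations for one feature vector; shape (4,), each in (0, 1)."""
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.W1.shape[1]:
            raise ValueError(f"feature dim {x.size} != network input dim {self.W1.shape[1]}")
        h = _sigmoid(self.W1 @ x + self.b1)
        return _sigmoid(self.W2 @ h + self.b2)

    def to_dict(self) -> dict:
        return {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "learning_rate": self.learning_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NNModel":
        return cls(
            np.asarray(d["W1"], float), np.asarray(d["b1"], float),
            np.asarray(d["W2"], float), np.asarray(d["b2"], float),
            float(d["learning_rate"]),
        )


def nn_loss_and_grads(
    model: NNModel, x: np.ndarray, target: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Squared-error loss 0.5*||o - t||^2 and its analytic gradients.

    Exposed so the backpropagation can be checked against finite
    differences; the training loop applies exactly these gradients.
    """
    x = np.asarray(x, dtype=float).ravel()
    t = np.asarray(target, dtype=float).ravel()
    h = _sigmoid(model.W1 @ x + model.b1)
    o = _sigmoid(model.W2 @ h + model.b2)
    err = o - t
    loss = 0.5 * float(err @ err)
    delta_o = err * o * (1.0 - o)
    delta_h = (model.W2.T @ delta_o) * h * (1.0 - h)
    grads = {
        "W2": np.outer(delta_o, h),
        "b2": delta_o,
        "W1": np.outer(delta_h, x),
        "b1": delta_h,
    }
    return loss, grads


def _one_hot(state: EmotionState) -> np.ndarray:
    t = np.zeros(len(STATE_ORDER))
    t[STATE_ORDER.index(EmotionState(state))] = 1.0
    return t


def train_nn(
    features: Sequence[np.ndarray],
    labels: Sequence[EmotionState],
    hp: HyperParams = HyperParams(),
    epochs: int = 200,
    seed: int = 0,
) -> NNModel:
    """Train the face network by seeded per-sample SGD.

    Weights start from U(-0.05, 0.05); each epoch visits the samples in a
    freshly shuffled (seeded) order and applies one gradient step per
    sample with learning rate ``hp.R``. Reproducible: identical data, seed
    and epochs give bit-identical weights.
    """
    X = np.asarray(list(features), dtype=float)
    if X.ndim != 2 or X.shape[1] != hp.D:
        raise ValueError(f"features must be (n, {hp.D}); got {X.shape}")
    y = [EmotionState(l) for l in labels]
    if len(y) != X.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows but {len(y)} labels")
    if len(set(y)) < 2:
        raise ValueError("need at least 2 emotion states in the training labels")
    targets = np.stack([_one_hot(l) for l in y])

    rng = np.random.default_rng(seed)
    model = NNModel(
        W1=rng.uniform(-0.05, 0.05, size=(hp.N, hp.D)),
        b1=rng.uniform(-0.05, 0.05, size=hp.N),
        W2=rng.uniform(-0.05, 0.05, size=(len(STATE_ORDER), hp.N)),
        b2=rng.uniform(-0.05, 0.05, size=len(STATE_ORDER)),
        learning_rate=hp.R,
    )
    for _ in range(epochs):
        for i in rng.permutation(X.shape[0]):
            _, g = nn_loss_and_grads(model, X[i], targets[i])
            model.W1 -= hp.R * g["W1"]
            model.b1 -= hp.R * g["b1"]
            model.W2 -= hp.R * g["W2"]
            model.b2 -= hp.R * g["b2"]
    return model


@dataclass(frozen=True)
class FaceScores:
    """Raw network outputs s1 and the decided state r1 (argmax of the
    min-max normalized scores, ties to the lowest index)."""

    s1: np.ndarray
    r1: EmotionState


def score_faces(nn: NNModel, feature: np.ndarray) -> FaceScores:
    """Score one projected face: four output activations + decision."""
    s1 = nn.forward(feature)
    return FaceScores(s1=s1, r1=fusion.decide(fusion.normalize_scores(s1)))


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    best: HyperParams
    scores: dict[HyperParams, float] = field(default_factory=dict)  # validation accuracy


def grid_search(
    train_images: Sequence[np.ndarray],
    train_labels: Sequence[EmotionState],
    val_images: Sequence[np.ndarray],
    val_labels: Sequence[EmotionState],
    grid: "dict[str, tuple] | None" = None,
    epochs: int = 200,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive search over the (D, N, R) Cartesian product.

    For every D a PCA is fitted once on the training images; each (N, R)
    pair then trains a network on the projected features and is scored by
    validation accuracy. Ties break toward smaller (D, N, R). Returns the
    winning hyperparameters plus the full score table.
    """
    if len(val_images) == 0:
        raise ValueError("validation set is empty")
    if len(train_images) == 0:
        raise ValueError("training set is empty")
    grid = dict(DEFAULT_GRID, **(grid or {}))
    result = GridSearchResult(best=HyperParams())
    best_key: "tuple | None" = None
    val_labels = [EmotionState(l) for l in val_labels]
    for D in sorted(grid["D"]):
        pca = fit_pca(train_images, D)
        train_feats = [project(pca, im) for im in train_images]
        val_feats = [project(pca, im) for im in val_images]
        for N, R in itertools.product(sorted(grid["N"]), sorted(grid["R"])):
            hp = HyperParams(D=D, N=N, R=R)
            nn = train_nn(train_feats, train_labels, hp=hp, epochs=epochs, seed=seed)
            hits = sum(
                score_faces(nn, f).r1 == l for f, l in zip(val_feats, val_labels)
            )
            acc = hits / len(val_labels)
            result.scores[hp] = acc
            key = (acc, -D, -N, -R)  # maximize accuracy; ties -> smaller hp
            if best_key is None or key > best_key:
                best_key = key
                result.best = hp
    return result


def save_face_model(path: "str | Path", pca: PCAModel, nn: NNModel, hp: HyperParams) -> None:
    Path(path).write_text(json.dumps({
        "pca": pca.to_dict(), "nn": nn.to_dict(),
        "hyperparams": {"D": hp.D, "N": hp.N, "R": hp.R},
    }))


def load_face_model(path: "str | Path") -> tuple[PCAModel, NNModel, HyperParams]:
    d = json.loads(Path(path).read_text())
    return (
        PCAModel.from_dict(d["pca"]),
        NNModel.from_dict(d["nn"]),
        HyperParams(**d["hyperparams"]),
    )
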