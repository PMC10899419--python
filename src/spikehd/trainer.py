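"""Adaptive class-hypervector training and prediction.

Each class is represented by one class HV, initialized to zero and updated
by iterating over the training trial HVs.  Updates are proportional to how
wrong (or how weakly right) the current model is: with ``l`` the true class,
``l'`` the predicted class, and ``d_l = cos(V, C_l)``,

* correct prediction:   ``C_l += eta * (1 - d_l) * V``
* misclassification:    ``C_l += eta * (d_l' - d_l) * V`` and
  ``C_l' -= eta * (d_l' - d_l) * V``.

The Gabor variant exploits the 9x9 spatial grid of classes: every update to
a center class is echoed, at a smaller rate ``eta_neighbor``, to the (up to
8) grid-adjacent classes of the center (and of the wrongly predicted class
in the error case).  Defaults follow the plain/grid variants' hyperparameters:
``eta = 0.01``, 3 epochs for natural scenes; ``eta_center = 0.01``,
``eta_neighbor = 0.001``, 2 epochs for Gabor.

Prediction assigns a trial to the class whose HV has the largest cosine
similarity to the trial HV; ties (including the all-zero initial model, for
which every similarity is 0) resolve to the lowest class index.  Class HVs
are kept as raw sums — no renormalization between updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import N_CLASSES, gabor_grid_xy

__all__ = [
    "ClassModel",
    "grid_adjacency",
    "predict",
    "predict_batch",
    "train_scenes",
    "train_gabor",
]


@dataclass
class ClassModel:
    """The ``m`` class hypervectors of one trained (or blank) classifier."""

    class_hvs: np.ndarray  # (m, D)
    task: str
    hyperparams: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.class_hvs.shape[0]

    @classmethod
    def blank(cls, m: int, D: int, task: str) -> "ClassModel":
        return cls(np.zeros((m, D)), task)


def grid_adjacency(side: int = 9) -> list[np.ndarray]:
    """8-connected neighbor lists for classes on a ``side x side`` grid.

    Corner classes have 3 neighbors, edge classes 5, interior classes 8.
    """
    labels = np.arange(side * side)
    x, y = labels % side, labels // side
    neighbors = []
    for lbl in labels:
        dx = np.abs(x - x[lbl])
        dy = np.abs(y - y[lbl])
        adj = (dx <= 1) & (dy <= 1) & (labels != lbl)
        neighbors.append(labels[adj])
    return neighbors


def _similarities(v: np.ndarray, class_hvs: np.ndarray) -> np.ndarray:
    """Cosine similarity of ``v`` to each class HV; zero-norm rows score 0.

    Denominator is ``sqrt(|c|^2 |v|^2)``, which makes the similarity of a
    vector with a positive multiple of itself exactly 1.0 — the zero-update
    fixed point of training then holds bit-exactly.
    """
    sq = np.einsum("ij,ij->i", class_hvs, class_hvs)
    vv = float(v @ v)
    if vv == 0.0:
        return np.zeros(class_hvs.shape[0])
    denom = np.sqrt(sq * vv)
    safe = np.where(denom > 0, denom, 1.0)
    return np.where(denom > 0, (class_hvs @ v) / safe, 0.0)


def predict(v: np.ndarray, model: ClassModel) -> int:
    """Most similar class; ties go to the lowest class index."""
    return int(np.argmax(_similarities(v, model.class_hvs)))


def predict_batch(trial_hvs: np.ndarray, model: ClassModel) -> np.ndarray:
    csq = np.einsum("ij,ij->i", model.class_hvs, model.class_hvs)
    vsq = np.einsum("ij,ij->i", trial_hvs, trial_hvs)
    denom = np.sqrt(vsq[:, None] * csq[None, :])
    safe = np.where(denom > 0, denom, 1.0)
    sims = np.where(denom > 0, (trial_hvs @ model.class_hvs.T) / safe, 0.0)
    return np.argmax(sims, axis=1)


def _check_labels(labels: np.ndarray, m: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 0 or labels.max() >= m):
        raise ValueError(f"labels must lie in [0, {m})")
    return labels


def _epoch_order(n: int, epoch: int, rng: np.random.Generator | None) -> np.ndarray:
    return np.arange(n) if rng is None else rng.permutation(n)


def train_scenes(
    trial_hvs: np.ndarray,
    labels: np.ndarray,
    model: ClassModel | None = None,
    eta: float = 0.01,
    epochs: int = 3,
    m: int = N_CLASSES["natural_scenes"],
    shuffle_seed: int | None = 0,
) -> ClassModel:
    """Plain adaptive training (one class per natural-scene image).

    Samples are visited in a freshly shuffled order each epoch (seeded;
    ``shuffle_seed=None`` keeps the given order).  Training is deterministic
    given (data, seed).
    """
    trial_hvs = np.asarray(trial_hvs, dtype=np.float64)
    labels = _check_labels(labels, m)
    if model is None:
        model = ClassModel.blank(m, trial_hvs.shape[1], "natural_scenes")
    model.hyperparams = {"eta": eta, "epochs": epochs}
    C = model.class_hvs
    rng = None if shuffle_seed is None else np.random.default_rng(shuffle_seed)
    for epoch in range(epochs):
        for k in _epoch_order(len(labels), epoch, rng):
            v = trial_hvs[k]
            sims = _similarities(v, C)
            pred = int(np.argmax(sims))
            true = int(labels[k])
            d_true, d_pred = sims[true], sims[pred]
            if pred == true:
                C[true] += eta * (1.0 - d_true) * v
            else:
                C[true] += eta * (d_pred - d_true) * v
                C[pred] -= eta * (d_pred - d_true) * v
    return model


def train_gabor(
    trial_hvs: np.ndarray,
    labels: np.ndarray,
    model: ClassModel | None = None,
    adjacency: list[np.ndarray] | None = None,
    eta_center: float = 0.01,
    eta_neighbor: float = 0.001,
    epochs: int = 2,
    shuffle_seed: int | None = 0,
) -> ClassModel:
    """Grid-aware adaptive training for the 81 Gabor locations.

    Every center update is propagated to grid-adjacent classes at rate
    ``eta_neighbor``.  In the error case the four update lines (center +,
    center's neighbors +, predicted -, predicted's neighbors -) are applied
    additively in that order, so a class that appears in several roles
    (e.g. adjacent to both the true and the predicted class) accumulates
    each contribution.
    """
    trial_hvs = np.asarray(trial_hvs, dtype=np.float64)
    m = N_CLASSES["gabor"]
    labels = _check_labels(labels, m)
    if adjacency is None:
        adjacency = grid_adjacency()
    if model is None:
        model = ClassModel.blank(m, trial_hvs.shape[1], "gabor")
    model.hyperparams = {
        "eta_center": eta_center,
        "eta_neighbor": eta_neighbor,
        "epochs": epochs,
    }
    C = model.class_hvs
    rng = None if shuffle_seed is None else np.random.default_rng(shuffle_seed)
    for epoch in range(epochs):
        for k in _epoch_order(len(labels), epoch, rng):
            v = trial_hvs[k]
            sims = _similarities(v, C)
            pred = int(np.argmax(sims))
            true = int(labels[k])
            d_true, d_pred = sims[true], sims[pred]
            if pred == true:
                gain = 1.0 - d_true
                C[true] += eta_center * gain * v
                for nb in adjacency[true]:
                    C[nb] += eta_neighbor * gain * v
            else:
                gain = d_pred - d_true
                C[true] += eta_center * gain * v
                for nb in adjacency[true]:
                    C[nb] += eta_neighbor * gain * v
                C[pred] -= eta_center * gain * v
                for nb in adjacency[pred]:
                    C[nb] -= eta_neighbor * gain * v
    return model
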