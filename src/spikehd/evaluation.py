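"""Accuracy metrics, chance levels, data augmentation, and statistics.

* Natural scenes: per-class one-vs-rest F1 scores and their macro mean;
  uniform random guessing over ``m`` balanced classes gives macro F1 of
  ``1/m`` (0.008 for 118 classes).
* Gabor locations: the per-trial Euclidean distance between the true and
  predicted cell of the 9x9 grid; guessing gives a mean error of about 4.7
  (computed here by exact enumeration over all 81 x 81 pairs).
* Data augmentation: within one class, trial indices are shuffled uniformly
  across neurons and independently per time bin, generating surrogate trials
  that preserve every per-(neuron, time) count distribution while breaking
  only cross-time noise correlations; four shuffled copies plus the original
  give a 5-fold sample expansion.
* Per-subject optimal-resolution selection: the resolution with the lowest
  median paired error, plus every resolution statistically indistinguishable
  from it (paired Wilcoxon signed rank, p >= alpha), all counted into the
  group-level histogram.
* Pearson correlation significance via a permutation randomization test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

from .data import gabor_grid_xy

__all__ = [
    "EvalResult",
    "f1_scores",
    "chance_f1",
    "euclid_errors",
    "gabor_chance_error",
    "augment_trials",
    "wilcoxon_paired",
    "select_optimal_resolution",
    "group_level_histogram",
    "pearson_randomization_test",
]


@dataclass
class EvalResult:
    """Decoding outcome at one spatiotemporal resolution.

    ``per_trial_errors`` holds the paired per-trial quantity used for
    resolution comparisons: the Euclidean grid error for the Gabor task, the
    0/1 misclassification indicator for natural scenes.  ``per_class_f1``
    is filled for the scenes task.
    """

    task: str
    resolution: object
    per_trial_errors: np.ndarray
    accuracy: float
    per_class_f1: np.ndarray | None = None
    macro_f1: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.per_trial_errors))

    @property
    def median_error(self) -> float:
        return float(np.median(self.per_trial_errors))


def f1_scores(true_labels, pred_labels, m: int) -> tuple[np.ndarray, float]:
    """Per-class one-vs-rest F1 and the macro mean over all ``m`` classes.

    Classes absent from both truth and prediction score F1 = 0 (not
    skipped), so the macro mean is always over ``m`` terms.
    """
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.size and (min(true_labels.min(), pred_labels.min()) < 0
                             or max(true_labels.max(), pred_labels.max()) >= m):
        raise ValueError(f"labels must lie in [0, {m})")
    _, _, f1, _ = precision_recall_fscore_support(
        true_labels, pred_labels, labels=np.arange(m), zero_division=0
    )
    return f1, float(f1.mean())


def chance_f1(m: int) -> float:
    """Macro F1 of uniform random guessing over ``m`` balanced classes.

    Precision and recall both converge to ``1/m``, hence F1 -> ``1/m``.
    """
    return 1.0 / m


def euclid_errors(true_labels, pred_labels) -> np.ndarray:
    """Per-trial Euclidean distance between true and predicted grid cells."""
    tx, ty = gabor_grid_xy(np.asarray(true_labels))
    px, py = gabor_grid_xy(np.asarray(pred_labels))
    return np.sqrt((tx - px) ** 2.0 + (ty - py) ** 2.0)


def gabor_chance_error(n_cells: int = 81) -> float:
    """Mean grid error of uniform guessing, by exact enumeration (~4.7).

    Averages the distance over all ``81 x 81`` (true, predicted) cell pairs,
    each equally likely under independent uniform truth and guess.
    """
    labels = np.arange(n_cells)
    t, p = np.meshgrid(labels, labels, indexing="ij")
    return float(np.mean(euclid_errors(t.ravel(), p.ravel())))


def augment_trials(
    counts: np.ndarray, copies: int = 4, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Shuffle-based augmentation of one class's count array ``(N, T, K)``.

    For each copy and each time bin, one permutation of the ``K`` trial
    indices is applied to all ``N`` neurons at once, producing surrogate
    trials that mix real per-bin population states across repetitions of the
    same stimulus.  Output is ``(N, T, (copies + 1) * K)`` with the original
    trials first.  Must be applied separately to training and test
    partitions so surrogates never straddle the split.  ``K < 2`` is a no-op
    (nothing to shuffle) and warns.
    """
    counts = np.asarray(counts)
    if counts.ndim != 3:
        raise ValueError("expected a (neurons, time, trials) array")
    N, T, K = counts.shape
    if K < 2:
        import warnings

        warnings.warn("augment_trials: fewer than 2 trials; returning input unchanged")
        return counts.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocks = [counts]
    for _ in range(copies):
        shuffled = np.empty_like(counts)
        for t in range(T):
            shuffled[:, t, :] = counts[:, t, rng.permutation(K)]
        blocks.append(shuffled)
    return np.concatenate(blocks, axis=2)


def wilcoxon_paired(x, y) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value with zero differences
    dropped; exact null for small samples without ties, normal approximation
    otherwise.  All-zero differences (identical vectors) give p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if np.all(x == y):
        return 1.0
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.pvalue)


def select_optimal_resolution(
    per_resolution_errors: dict, alpha: float = 0.05
) -> set:
    """Per-subject optimal set of resolutions from paired per-trial errors.

    The resolution with the lowest median error is always optimal; every
    other resolution whose paired Wilcoxon test against it is insignificant
    (p >= alpha) joins the set — "jointly optimal" resolutions all count.
    Median ties (common for 0/1 misclassification errors) are broken by the
    mean, so "best" always denotes a genuinely lowest-error resolution.
    Error vectors must be paired (same trials, same order, equal length).
    """
    if not per_resolution_errors:
        raise ValueError("no resolutions supplied")
    lengths = {len(v) for v in per_resolution_errors.values()}
    if len(lengths) != 1:
        raise ValueError("per-trial error vectors must be paired (equal lengths)")
    best = min(
        per_resolution_errors,
        key=lambda k: (
            float(np.median(per_resolution_errors[k])),
            float(np.mean(per_resolution_errors[k])),
        ),
    )
    optimal = {best}
    for key, errs in per_resolution_errors.items():
        if key == best:
            continue
        if wilcoxon_paired(errs, per_resolution_errors[best]) >= alpha:
            optimal.add(key)
    return optimal


def group_level_histogram(per_subject_optimal_sets, resolutions) -> dict:
    """Count, per resolution, the subjects whose optimal set contains it.

    A subject with several jointly-optimal resolutions contributes to each
    of their bins.
    """
    hist = {r: 0 for r in resolutions}
    for opt in per_subject_optimal_sets:
        for r in opt:
            if r in hist:
                hist[r] += 1
    return hist


def pearson_randomization_test(
    x, y, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Pearson r with a two-sided permutation p-value.

    ``y`` is permuted ``n_perm`` times;
    ``p = (1 + #{perm: |r_perm| >= |r|}) / (1 + n_perm)``, so the smallest
    attainable p is ``1/(n_perm + 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input has no defined correlation")
    r = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    hits = 0
    for _ in range(n_perm):
        r_perm = float(xc @ rng.permutation(yc) / denom)
        if abs(r_perm) >= abs(r) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return r, p
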