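"""End-to-end decoding workflows: encode, cross-validate, sweep resolutions.

The central question these workflows answer is *which spatiotemporal
resolution of the spike counts maximizes decoding accuracy*: spike counts
are binned and spatially pooled at one :class:`ResolutionConfig`, encoded
into trial hypervectors, decoded under stratified cross-validation with the
adaptive trainer, and the per-trial errors compared across resolutions with
the paired selection rule of :mod:`spikehd.evaluation`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data import N_CLASSES, SpikeDataset, receptive_field_matrix
from .encoder import EncoderState, build_spatial_hvs, encode_trials
from .evaluation import (
    EvalResult,
    augment_trials,
    euclid_errors,
    f1_scores,
    select_optimal_resolution,
)
from .hdc import HDConfig
from .resolution import (
    BinnedTensor,
    ResolutionConfig,
    aggregate_spatial,
    bin_temporal,
    cluster_populations,
    fano_factor,
)
from .trainer import train_gabor, train_scenes, predict_batch

__all__ = [
    "DecodeSettings",
    "decode_at_resolution",
    "scan_resolutions",
    "regional_optimal_bins",
    "config_hash",
]


@dataclass(frozen=True)
class DecodeSettings:
    """Cross-validation, augmentation, and trainer settings for one run."""

    n_folds: int = 5
    augment_copies: int = 0
    eta: float = 0.01
    eta_center: float = 0.01
    eta_neighbor: float = 0.001
    epochs_scenes: int = 3
    epochs_gabor: int = 2
    normalize_by_units: bool = False
    seed: int = 0


def config_hash(*objs) -> str:
    """Short stable hash of the run configuration, embedded in outputs."""
    blob = json.dumps([asdict(o) if hasattr(o, "__dataclass_fields__") else o for o in objs],
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _prepare_tensor(
    ds: SpikeDataset, task: str, res: ResolutionConfig
) -> tuple[BinnedTensor, np.ndarray, np.ndarray]:
    """Bin and spatially aggregate the task's trials; returns the tensor,
    the class labels, and the original trial ids (time-HV keys)."""
    mask = ds.task_mask(task)
    if not mask.any():
        raise ValueError(f"dataset contains no {task!r} trials")
    sub = ds.subset_trials(mask)
    bt = bin_temporal(
        sub.counts, res.bin_size_ms, res.bin_mode,
        unit_labels=list(ds.units["unit_id"]),
    )
    if res.spatial_level != "neuron":
        ei = None
        if res.spatial_level == "population":
            ei = cluster_populations(ds.units, fano_factor(ds, res.fano_bin_ms))
        bt = aggregate_spatial(bt, res.spatial_level, ds.units, ei)
    labels = sub.trials["class_label"].to_numpy()
    trial_ids = sub.trials["trial_id"].to_numpy()
    return bt, labels, trial_ids


def decode_at_resolution(
    ds: SpikeDataset,
    task: str,
    res: ResolutionConfig,
    hd: HDConfig,
    settings: DecodeSettings = DecodeSettings(),
    n_classes: int | None = None,
) -> EvalResult:
    """Cross-validated decoding accuracy at one spatiotemporal resolution.

    Trials of ``task`` are binned/pooled per ``res``, encoded (independent
    per-trial time HVs unless ``res.shared_time_hvs``), and decoded with
    stratified ``n_folds``-fold cross-validation.  With ``augment_copies >
    0`` each fold's training and test partitions are expanded separately by
    shuffle augmentation (copies + 1 samples per original trial); augmented
    copies inherit their source partition, so no surrogate straddles the
    train/test split.  Per-trial errors are returned in an order that is
    reproducible and identical across resolutions, making them valid paired
    inputs to :func:`spikehd.evaluation.select_optimal_resolution`.
    """
    bt, labels, trial_ids = _prepare_tensor(ds, task, res)
    m = n_classes if n_classes is not None else N_CLASSES[task]

    state = EncoderState(
        hd,
        time_mode="shared" if res.shared_time_hvs else "independent_per_trial",
        normalize_by_units=settings.normalize_by_units,
    )
    rf = units = None
    if res.spatial_level == "neuron":
        units = ds.units
        rf = receptive_field_matrix(ds)
    S = build_spatial_hvs(state, bt, units=units, rf_matrix=rf)
    orig_hvs = encode_trials(bt, S, state, [f"trial/{t}" for t in trial_ids])

    skf = StratifiedKFold(n_splits=settings.n_folds, shuffle=True, random_state=settings.seed)
    all_true, all_pred = [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        train_hvs, train_y = [orig_hvs[train_idx]], [labels[train_idx]]
        test_hvs, test_y = [orig_hvs[test_idx]], [labels[test_idx]]
        if settings.augment_copies > 0:
            for part, idx, hv_list, y_list in (
                ("train", train_idx, train_hvs, train_y),
                ("test", test_idx, test_hvs, test_y),
            ):
                for cls in np.unique(labels[idx]):
                    src = idx[labels[idx] == cls]
                    if src.size < 2:
                        continue
                    # permutation rng depends only on (seed, fold, part, class):
                    # identical trial mixtures across resolutions -> paired errors
                    rng = np.random.default_rng(
                        [settings.seed, fold, int(cls), 0 if part == "train" else 1]
                    )
                    aug = augment_trials(bt.counts[:, :, src], settings.augment_copies, rng)
                    aug = aug[:, :, src.size:]  # originals already encoded
                    aug_bt = BinnedTensor(aug, bt.unit_labels, bt.bin_size_ms,
                                          bt.spatial_level, bt.bin_mode)
                    keys = [f"aug/{part}/{fold}/{cls}/{j}" for j in range(aug.shape[2])]
                    hv_list.append(encode_trials(aug_bt, S, state, keys))
                    y_list.append(np.full(aug.shape[2], cls))
        train_X = np.concatenate(train_hvs)
        train_lab = np.concatenate(train_y)
        if task == "gabor":
            model = train_gabor(
                train_X, train_lab,
                eta_center=settings.eta_center, eta_neighbor=settings.eta_neighbor,
                epochs=settings.epochs_gabor, shuffle_seed=settings.seed + fold,
            )
        else:
            model = train_scenes(
                train_X, train_lab, m=m,
                eta=settings.eta, epochs=settings.epochs_scenes,
                shuffle_seed=settings.seed + fold,
            )
        all_true.append(np.concatenate(test_y))
        all_pred.append(predict_batch(np.concatenate(test_hvs), model))

    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    accuracy = float(np.mean(y_true == y_pred))
    if task == "gabor":
        errors = euclid_errors(y_true, y_pred)
        return EvalResult(task, res, errors, accuracy)
    per_class, macro = f1_scores(y_true, y_pred, m)
    errors = (y_true != y_pred).astype(float)
    return EvalResult(task, res, errors, accuracy, per_class_f1=per_class, macro_f1=macro)


def scan_resolutions(
    ds: SpikeDataset,
    task: str,
    resolutions: list[ResolutionConfig],
    hd: HDConfig,
    settings: DecodeSettings = DecodeSettings(),
    n_classes: int | None = None,
    alpha: float = 0.05,
    subject: str = "subject0",
) -> dict:
    """Decode at every resolution and select the per-subject optimal set.

    Returns ``{"results": tidy DataFrame, "evals": {res: EvalResult},
    "optimal": set, "config_hash": str}``.  The tidy table has one row per
    (resolution, metric) with the config hash in a column.
    """
    evals: dict[ResolutionConfig, EvalResult] = {}
    for res in resolutions:
        evals[res] = decode_at_resolution(ds, task, res, hd, settings, n_classes)
    optimal = select_optimal_resolution(
        {res: ev.per_trial_errors for res, ev in evals.items()}, alpha=alpha
    )
    chash = config_hash(hd, settings, *resolutions, task)
    rows = []
    for res, ev in evals.items():
        metrics = {
            "mean_error": ev.mean_error,
            "median_error": ev.median_error,
            "accuracy": ev.accuracy,
        }
        if ev.macro_f1 is not None:
            metrics["macro_f1"] = ev.macro_f1
        for name, value in metrics.items():
            rows.append(
                {
                    "subject": subject,
                    "task": task,
                    "spatial_level": res.spatial_level,
                    "bin_size_ms": res.bin_size_ms,
                    "bin_mode": res.bin_mode,
                    "metric": name,
                    "value": value,
                    "optimal": res in optimal,
                    "config_hash": chash,
                }
            )
    return {
        "results": pd.DataFrame(rows),
        "evals": evals,
        "optimal": optimal,
        "config_hash": chash,
    }


def regional_optimal_bins(
    ds: SpikeDataset,
    bin_sizes: list[int],
    hd: HDConfig,
    settings: DecodeSettings = DecodeSettings(),
    task: str = "gabor",
    spatial_level: str = "area",
    alpha: float = 0.05,
) -> dict:
    """Optimal temporal bin size per brain region, decoding one region at a
    time at a fixed (default area) spatial level.

    For a region with several jointly-optimal bins the smallest-median one
    (the set's representative) plus the full set are both reported.
    Returns ``{region: {"optimal_set": set, "best": int}}``.
    """
    out = {}
    for region in ds.units["region"].unique():
        sub = ds.subset_units((ds.units["region"] == region).to_numpy())
        errors = {}
        for b in bin_sizes:
            res = ResolutionConfig(bin_size_ms=b, spatial_level=spatial_level)
            ev = decode_at_resolution(sub, task, res, hd, settings)
            errors[b] = ev.per_trial_errors
        opt = select_optimal_resolution(errors, alpha=alpha)
        best = min(opt, key=lambda b: np.median(errors[b]))
        out[region] = {"optimal_set": opt, "best": best}
    return out
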