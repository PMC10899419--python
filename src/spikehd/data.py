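"""Data model and CSV I/O for units, trials, and 1 ms-binned spike counts.

The in-memory container is :class:`SpikeDataset`: a units table (unit id,
brain area, brain region), a trials table (trial id, task, class label), and
a dense integer count tensor of shape ``(n_units, 250, n_trials)`` holding
spike counts in 1 ms bins over the 250 ms trial window.

Two visual tasks are modeled, matching the structure of large-scale mouse
Neuropixels visual-coding experiments:

* ``gabor`` — a Gabor patch flashed at one of 81 positions on a 9x9 grid
  (classes 0..80, by default 45 repetitions per position);
* ``natural_scenes`` — one of 118 grayscale natural images
  (classes 0..117, by default 50 repetitions per image).

Brain areas are mapped to regions through :data:`AREA_TO_REGION`; unknown
areas are rejected unless the caller supplies an explicit mapping.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_MS",
    "TASKS",
    "N_CLASSES",
    "AREA_TO_REGION",
    "REGIONS",
    "SpikeDataset",
    "gabor_grid_xy",
    "read_dataset",
    "write_dataset",
    "receptive_field_matrix",
]

TRIAL_MS = 250

TASKS = ("gabor", "natural_scenes")
N_CLASSES = {"gabor": 81, "natural_scenes": 118}

#: Brain areas grouped into regions (visual cortex, hippocampal formation,
#: thalamus, hypothalamus, midbrain) as recorded in the mouse visual-coding
#: Neuropixels preparation.
AREA_TO_REGION: dict[str, str] = {
    "VISp": "Striate cortex",
    "VISam": "Dorsal extrastriate cortex",
    "VISal": "Dorsal extrastriate cortex",
    "VISrl": "Dorsal extrastriate cortex",
    "VISmma": "Dorsal extrastriate cortex",
    "VISpm": "Ventral extrastriate cortex",
    "VISl": "Ventral extrastriate cortex",
    "CA1": "Hippocampus",
    "CA2": "Hippocampus",
    "CA3": "Hippocampus",
    "SUB": "Subiculum",
    "ProS": "Subiculum",
    "DG": "Dentate Gyrus",
    "TH": "Thalamus",
    "LP": "Thalamus",
    "LGv": "Thalamus",
    "LGd": "Thalamus",
    "PP": "Thalamus",
    "PIL": "Thalamus",
    "MGv": "Thalamus",
    "PO": "Thalamus",
    "Eth": "Thalamus",
    "POL": "Thalamus",
    "ZI": "Hypothalamus",
    "APN": "Midbrain",
}

REGIONS = tuple(dict.fromkeys(AREA_TO_REGION.values()))


def gabor_grid_xy(label: int | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map Gabor class labels to 9x9 grid coordinates, row-major.

    ``(x, y) = (label mod 9, label div 9)``.  The assignment of labels to
    grid cells is a convention of this package; any fixed bijection gives the
    same decoding problem.
    """
    label = np.asarray(label)
    return label % 9, label // 9


def _map_regions(areas: pd.Series, area_map: Mapping[str, str] | None) -> pd.Series:
    mapping = dict(AREA_TO_REGION)
    if area_map:
        mapping.update(area_map)
    unknown = sorted(set(areas) - set(mapping))
    if unknown:
        raise ValueError(
            f"unknown brain areas {unknown}; supply area_map={{area: region}} for "
            "areas outside the built-in region table"
        )
    return areas.map(mapping)


@dataclass
class SpikeDataset:
    """Units, trials, and 1 ms-binned spike counts for one subject.

    ``units`` has columns ``unit_id, area, region`` (unique unit ids);
    ``trials`` has ``trial_id, task, class_label`` (unique trial ids, labels
    within the task's class range); ``counts`` is an integer array of shape
    ``(n_units, 250, n_trials)`` aligned with the row order of both tables.
    """

    units: pd.DataFrame
    trials: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.units = self.units.reset_index(drop=True)
        self.trials = self.trials.reset_index(drop=True)
        if self.units["unit_id"].duplicated().any():
            raise ValueError("duplicate unit_id in units table")
        if self.trials["trial_id"].duplicated().any():
            raise ValueError("duplicate trial_id in trials table")
        bad_task = set(self.trials["task"]) - set(TASKS)
        if bad_task:
            raise ValueError(f"unknown task(s) {sorted(bad_task)}; expected {TASKS}")
        for task, grp in self.trials.groupby("task"):
            m = N_CLASSES[task]
            labels = grp["class_label"].to_numpy()
            if labels.min() < 0 or labels.max() >= m:
                raise ValueError(f"{task} class labels must lie in [0, {m})")
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integer-valued")
        expected = (len(self.units), TRIAL_MS, len(self.trials))
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def task_mask(self, task: str) -> np.ndarray:
        return (self.trials["task"] == task).to_numpy()

    def subset_trials(self, mask: np.ndarray) -> "SpikeDataset":
        """Dataset restricted to the trials selected by a boolean mask."""
        return SpikeDataset(
            self.units.copy(), self.trials.loc[mask].copy(), self.counts[:, :, mask]
        )

    def subset_units(self, mask: np.ndarray) -> "SpikeDataset":
        """Dataset restricted to the units selected by a boolean mask."""
        return SpikeDataset(
            self.units.loc[mask].copy(), self.trials.copy(), self.counts[mask]
        )


def _require_columns(df: pd.DataFrame, cols: list[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_dataset(
    events_path,
    units_path,
    trials_path,
    area_map: Mapping[str, str] | None = None,
) -> SpikeDataset:
    """Assemble a :class:`SpikeDataset` from three CSV tables.

    ``events``: ``unit_id, trial_id, time_ms`` — one row per spike, time in
    [0, 250) ms relative to trial start; each spike is floored into its 1 ms
    bin.  ``units``: ``unit_id, area``.  ``trials``: ``trial_id, task,
    class_label``.  Spikes referencing unknown ids, or with out-of-range
    times, raise errors naming the offending row numbers.
    """
    units = pd.read_csv(units_path)
    trials = pd.read_csv(trials_path)
    events = pd.read_csv(events_path)
    _require_columns(units, ["unit_id", "area"], str(units_path))
    _require_columns(trials, ["trial_id", "task", "class_label"], str(trials_path))
    _require_columns(events, ["unit_id", "trial_id", "time_ms"], str(events_path))

    units = units.copy()
    units["region"] = _map_regions(units["area"], area_map)

    t = events["time_ms"].to_numpy(dtype=float)
    bad = np.flatnonzero((t < 0) | (t >= TRIAL_MS) | ~np.isfinite(t))
    if bad.size:
        rows = (bad[:10] + 2).tolist()  # 1-based, +1 for header
        raise ValueError(
            f"{events_path}: spike times outside [0, {TRIAL_MS}) ms at file row(s) {rows}"
            + ("..." if bad.size > 10 else "")
        )

    unit_index = pd.Series(np.arange(len(units)), index=units["unit_id"])
    trial_index = pd.Series(np.arange(len(trials)), index=trials["trial_id"])
    ui = events["unit_id"].map(unit_index)
    ti = events["trial_id"].map(trial_index)
    for name, idx in (("unit_id", ui), ("trial_id", ti)):
        bad = np.flatnonzero(idx.isna().to_numpy())
        if bad.size:
            rows = (bad[:10] + 2).tolist()
            raise ValueError(
                f"{events_path}: unknown {name} at file row(s) {rows}"
                + ("..." if bad.size > 10 else "")
            )

    counts = np.zeros((len(units), TRIAL_MS, len(trials)), dtype=np.int32)
    np.add.at(
        counts,
        (ui.to_numpy(dtype=np.intp), np.floor(t).astype(np.intp), ti.to_numpy(dtype=np.intp)),
        1,
    )
    return SpikeDataset(units, trials, counts)


def write_dataset(ds: SpikeDataset, dir_path) -> dict[str, str]:
    """Write a dataset as ``events.csv``, ``units.csv``, ``trials.csv``.

    Each spike count ``c`` in a 1 ms bin becomes ``c`` event rows at the bin's
    left edge, so ``read_dataset(**write_dataset(ds))`` reproduces ``counts``
    bit-exactly.  Returns the three paths keyed by ``read_dataset`` argument
    name.
    """
    os.makedirs(dir_path, exist_ok=True)
    paths = {
        "events_path": os.path.join(dir_path, "events.csv"),
        "units_path": os.path.join(dir_path, "units.csv"),
        "trials_path": os.path.join(dir_path, "trials.csv"),
    }
    ds.units[["unit_id", "area"]].to_csv(paths["units_path"], index=False)
    ds.trials[["trial_id", "task", "class_label"]].to_csv(paths["trials_path"], index=False)

    ui, ti_bin, ki = np.nonzero(ds.counts)
    reps = ds.counts[ui, ti_bin, ki]
    events = pd.DataFrame(
        {
            "unit_id": np.repeat(ds.units["unit_id"].to_numpy()[ui], reps),
            "trial_id": np.repeat(ds.trials["trial_id"].to_numpy()[ki], reps),
            "time_ms": np.repeat(ti_bin.astype(float), reps),
        }
    )
    events.to_csv(paths["events_path"], index=False)
    return paths


def receptive_field_matrix(
    ds: SpikeDataset, trial_mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-unit receptive-field fingerprints from the Gabor task.

    For each unit, the mean total spike count over the full 250 ms trial for
    each of the 81 Gabor grid positions, averaged over that position's
    repetitions — an ``(n_units, 81)`` array.  ``trial_mask`` optionally
    restricts which trials are used for tuning (e.g. to keep tuning trials
    disjoint from decoding trials).
    """
    mask = ds.task_mask("gabor")
    if trial_mask is not None:
        mask = mask & np.asarray(trial_mask, dtype=bool)
    if not mask.any():
        raise ValueError("receptive_field_matrix requires gabor trials")
    labels = ds.trials.loc[mask, "class_label"].to_numpy()
    missing = sorted(set(range(N_CLASSES["gabor"])) - set(labels.tolist()))
    if missing:
        raise ValueError(f"gabor classes with zero trials: {missing}")
    totals = ds.counts[:, :, mask].sum(axis=1)  # units x trials
    F = np.empty((ds.n_units, N_CLASSES["gabor"]), dtype=np.float64)
    for lbl in range(N_CLASSES["gabor"]):
        F[:, lbl] = totals[:, labels == lbl].mean(axis=1)
    return F
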