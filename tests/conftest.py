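"""Shared fixtures: small programmatically-built spike datasets."""

import numpy as np
import pandas as pd
import pytest

from spikehd.data import N_CLASSES, TRIAL_MS, AREA_TO_REGION, SpikeDataset


def build_dataset(units_spec, trials_spec, fill=None, seed=0):
    """Construct a SpikeDataset directly from specs.

    units_spec: list of (unit_id, area); trials_spec: list of
    (trial_id, task, class_label).  ``fill`` optionally maps
    (unit_idx, trial_idx) -> 250-vector of counts; default all zeros.
    """
    units = pd.DataFrame(
        {
            "unit_id": [u for u, _ in units_spec],
            "area": [a for _, a in units_spec],
        }
    )
    units["region"] = units["area"].map(AREA_TO_REGION)
    trials = pd.DataFrame(
        {
            "trial_id": [t for t, _, _ in trials_spec],
            "task": [tk for _, tk, _ in trials_spec],
            "class_label": [c for _, _, c in trials_spec],
        }
    )
    counts = np.zeros((len(units), TRIAL_MS, len(trials)), dtype=np.int32)
    if fill is not None:
        for (ui, ti), vec in fill.items():
            counts[ui, :, ti] = vec
    return SpikeDataset(units, trials, counts)


def poisson_gabor_dataset(n_units=4, reps=2, rate_per_ms=0.02, seed=0, areas=None):
    """All 81 gabor classes x reps trials with homogeneous Poisson units."""
    rng = np.random.default_rng(seed)
    if areas is None:
        areas = ["VISp"] * n_units
    units = pd.DataFrame(
        {"unit_id": np.arange(n_units), "area": areas}
    )
    units["region"] = units["area"].map(AREA_TO_REGION)
    labels = np.repeat(np.arange(N_CLASSES["gabor"]), reps)
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(labels.size),
            "task": "gabor",
            "class_label": labels,
        }
    )
    counts = rng.poisson(rate_per_ms, size=(n_units, TRIAL_MS, labels.size)).astype(np.int32)
    return SpikeDataset(units, trials, counts)


@pytest.fixture(scope="session")
def tiny_gabor_ds():
    return poisson_gabor_dataset(n_units=6, reps=2, seed=11,
                                 areas=["VISp", "VISp", "VISam", "VISam", "CA1", "CA1"])
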