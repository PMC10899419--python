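"""Temporal binning and the five-level spatial aggregation of spike counts.

Decoding accuracy is compared across a grid of spatiotemporal resolutions:

* **temporal** — 1 ms base counts are summed into bins of 1, 2, 5, 10, 25,
  50, 125 or 250 ms (the divisors of the 250 ms trial).  Non-divisor bin
  sizes are supported through two compromise modes: ``overlap`` (bins may
  overlap so the whole trial is covered; spikes can be counted twice) and
  ``crop`` (disjoint bins; the trailing remainder of the trial is dropped).
* **spatial** — counts are pooled at one of five levels: ``neuron`` (no
  pooling), ``population`` (putatively excitatory/inhibitory populations
  within each area), ``area``, ``region``, or ``whole_brain``.

The E/I split uses the spike-count Fano factor (variance-to-mean ratio over
Gabor trials): within each area, the 20% of units with the highest Fano
factor are labeled putatively inhibitory (fast-spiking units fire more
irregularly), the rest putatively excitatory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import TRIAL_MS, SpikeDataset

__all__ = [
    "SPATIAL_LEVELS",
    "DIVISOR_BIN_SIZES",
    "ResolutionConfig",
    "BinnedTensor",
    "bin_starts",
    "bin_temporal",
    "fano_factor",
    "cluster_populations",
    "aggregate_spatial",
]

SPATIAL_LEVELS = ("neuron", "population", "area", "region", "whole_brain")
DIVISOR_BIN_SIZES = (1, 2, 5, 10, 25, 50, 125, 250)
BIN_MODES = ("exact", "overlap", "crop")


@dataclass(frozen=True)
class ResolutionConfig:
    """One point of the spatiotemporal-resolution grid.

    ``fano_bin_ms`` is the bin size used when computing Fano factors for the
    population-level E/I split; it is a hyperparameter swept independently of
    ``bin_size_ms`` (the split can change with the timescale at which
    variability is measured).
    """

    bin_size_ms: int = 1
    spatial_level: str = "neuron"
    bin_mode: str = "exact"
    fano_bin_ms: int = 25
    shared_time_hvs: bool = False

    def __post_init__(self) -> None:
        if self.spatial_level not in SPATIAL_LEVELS:
            raise ValueError(f"spatial_level must be one of {SPATIAL_LEVELS}")
        if self.bin_mode not in BIN_MODES:
            raise ValueError(f"bin_mode must be one of {BIN_MODES}")
        if self.bin_size_ms < 1 or self.bin_size_ms > TRIAL_MS:
            raise ValueError(f"bin_size_ms must lie in [1, {TRIAL_MS}]")
        if self.bin_mode == "exact" and TRIAL_MS % self.bin_size_ms != 0:
            raise ValueError(
                f"bin_size_ms={self.bin_size_ms} does not divide {TRIAL_MS} ms; "
                "use bin_mode='overlap' or 'crop' for non-divisor bin sizes"
            )
        if TRIAL_MS % self.fano_bin_ms != 0:
            raise ValueError(f"fano_bin_ms must divide {TRIAL_MS} ms")


@dataclass
class BinnedTensor:
    """Spike counts at a working spatiotemporal resolution.

    ``counts`` has shape ``(n_spatial_units, M, n_trials)`` where ``M`` is
    the number of time bins; ``unit_labels`` names each spatial unit (a unit
    id at neuron level, ``"area/E"`` at population level, an area or region
    name, or ``"brain"``).
    """

    counts: np.ndarray
    unit_labels: list
    bin_size_ms: int
    spatial_level: str
    bin_mode: str = "exact"

    @property
    def M(self) -> int:
        return self.counts.shape[1]


def bin_starts(bin_size_ms: int, bin_mode: str, trial_ms: int = TRIAL_MS) -> np.ndarray:
    """Left edges of the time bins for the given size and mode.

    ``exact``/``crop``: consecutive disjoint bins from 0 (crop drops the
    trailing remainder).  ``overlap``: ``M = ceil(trial/size)`` bins with
    starts ``floor(j*(trial-size)/(M-1))`` so the first bin starts at 0 and
    the last ends exactly at the trial end; neighboring bins overlap when the
    size is not a divisor.
    """
    w = int(bin_size_ms)
    if bin_mode == "exact":
        if trial_ms % w != 0:
            raise ValueError(
                f"bin_size_ms={w} does not divide {trial_ms} ms; "
                "use bin_mode='overlap' or 'crop'"
            )
        return np.arange(0, trial_ms, w)
    if bin_mode == "crop":
        M = trial_ms // w
        if M < 1:
            raise ValueError(f"bin_size_ms={w} exceeds the {trial_ms} ms trial")
        return np.arange(M) * w
    if bin_mode == "overlap":
        M = math.ceil(trial_ms / w)
        if M == 1:
            return np.array([0])
        j = np.arange(M)
        return (j * (trial_ms - w)) // (M - 1)
    raise ValueError(f"unknown bin_mode {bin_mode!r}")


def bin_temporal(
    base_counts: np.ndarray,
    bin_size_ms: int,
    bin_mode: str = "exact",
    unit_labels: Sequence | None = None,
    spatial_level: str = "neuron",
) -> BinnedTensor:
    """Sum 1 ms base counts ``(units, 250, trials)`` into coarser time bins.

    In ``exact`` mode the bins partition the trial and the total spike count
    is conserved; ``overlap`` may double-count spikes and ``crop`` may drop
    spikes after the last full bin.
    """
    base_counts = np.asarray(base_counts)
    if base_counts.ndim != 3 or base_counts.shape[1] != TRIAL_MS:
        raise ValueError(f"expected (units, {TRIAL_MS}, trials) base counts")
    starts = bin_starts(bin_size_ms, bin_mode)
    w = int(bin_size_ms)
    csum = np.concatenate(
        [np.zeros_like(base_counts[:, :1, :]), np.cumsum(base_counts, axis=1)], axis=1
    )
    binned = np.stack([csum[:, s + w, :] - csum[:, s, :] for s in starts], axis=1)
    if unit_labels is None:
        unit_labels = list(range(base_counts.shape[0]))
    return BinnedTensor(binned, list(unit_labels), w, spatial_level, bin_mode)


def fano_factor(
    ds: SpikeDataset, fano_bin_ms: int = 25, ddof: int = 0
) -> np.ndarray:
    """Spike-count Fano factor (variance/mean) per unit over Gabor trials.

    Counts are binned at ``fano_bin_ms`` and pooled over every (time bin,
    Gabor position, repetition) sample before taking variance/mean.  Silent
    units (mean 0) get Fano 0, so they land in the putatively excitatory
    group: the inhibitory label is reserved for high-variability units.
    Population variance (``ddof=0``) by default.
    """
    mask = ds.task_mask("gabor")
    if not mask.any():
        raise ValueError("fano_factor requires gabor trials")
    bt = bin_temporal(ds.counts[:, :, mask], fano_bin_ms, "exact")
    samples = bt.counts.reshape(ds.n_units, -1).astype(np.float64)
    mean = samples.mean(axis=1)
    var = samples.var(axis=1, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        fano = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    return fano


def cluster_populations(
    units: pd.DataFrame, fano: np.ndarray, frac_inhibitory: float = 0.2
) -> np.ndarray:
    """Label units E/I within each area by Fano-factor rank.

    The ``ceil(frac * n)`` highest-Fano units of each area are labeled
    ``"I"`` (putatively inhibitory), the rest ``"E"``; ties at the boundary
    are broken by unit_id order (lower ids first among equal Fano values).
    An area with a single unit gets one I unit by the ceil rule.
    """
    fano = np.asarray(fano, dtype=float)
    if len(fano) != len(units):
        raise ValueError("fano must have one value per unit")
    labels = np.full(len(units), "E", dtype="<U1")
    areas = units["area"].to_numpy()
    unit_ids = units["unit_id"].to_numpy()
    for area in pd.unique(areas):
        idx = np.flatnonzero(areas == area)
        n_i = math.ceil(frac_inhibitory * idx.size)
        order = sorted(idx, key=lambda i: (-fano[i], unit_ids[i]))
        labels[order[:n_i]] = "I"
    return labels


def aggregate_spatial(
    bt: BinnedTensor,
    level: str,
    units: pd.DataFrame,
    ei_labels: np.ndarray | None = None,
) -> BinnedTensor:
    """Pool a neuron-level binned tensor to a coarser spatial level.

    Counts are summed within each group (E/I population per area, area,
    region, or the whole brain), conserving the total spike count.  Group
    labels are ``"{area}/{E|I}"``, area names, region names, or ``"brain"``.
    """
    if level not in SPATIAL_LEVELS:
        raise ValueError(f"level must be one of {SPATIAL_LEVELS}")
    if bt.spatial_level != "neuron":
        if bt.spatial_level == level:
            return bt
        raise ValueError("aggregate_spatial expects a neuron-level tensor")
    if level == "neuron":
        return bt
    if len(units) != bt.counts.shape[0]:
        raise ValueError("units table does not match tensor rows")

    if level == "whole_brain":
        groups = pd.Series(["brain"] * len(units))
    elif level == "region":
        groups = units["region"]
    elif level == "area":
        groups = units["area"]
    else:  # population
        if ei_labels is None:
            raise ValueError("population level requires ei_labels (see cluster_populations)")
        groups = units["area"].astype(str) + "/" + pd.Series(np.asarray(ei_labels))
    group_names = list(dict.fromkeys(groups))
    out = np.zeros((len(group_names), bt.M, bt.counts.shape[2]), dtype=bt.counts.dtype)
    for gi, name in enumerate(group_names):
        out[gi] = bt.counts[(groups == name).to_numpy()].sum(axis=0)
    return BinnedTensor(out, group_names, bt.bin_size_ms, level, bt.bin_mode)
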