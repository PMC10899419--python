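"""Synthetic spike datasets with controllable signal structure.

The generator emulates the structure of a mouse visual-coding Neuropixels
session — 250 ms trials, a Gabor task (81 grid positions x 45 repetitions)
and a natural-scenes task (118 images x 50 repetitions), units assigned to
named brain areas that map onto regions — while exposing the knobs the
decoding analyses need to be tested against ground truth:

* **class signal**: per unit and class, the firing rate is
  ``base_rate * (1 + signal_gain * s_{i,c}(w))`` with the template ``s``
  piecewise-constant over windows of ``signal_timescale_ms``.  For the
  Gabor task the templates are spatially smooth over the 9x9 stimulus grid
  (a synthetic receptive field); when a trial has more than one window the
  window-varying part of the template is zero-mean across windows, so the
  class information genuinely lives at the configured timescale.
* **noise correlation**: a shared per-(area, trial, window) log-normal gain
  multiplies all rates within an area, inducing within-area count
  correlations (``noise_corr`` is the coefficient of variation of the gain).
* **E/I structure**: a fraction of units per area is inhibitory; their
  counts are negative-binomial with variance inflated by
  ``inhib_dispersion`` (matched mean), the minimal mechanism that gives the
  Fano-factor separation the population-level clustering relies on.
  Excitatory units are Poisson.
* **oscillation** (optional): a sinusoidal rate modulation whose phase runs
  continuously across trials, for testing spectral peak recovery.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import N_CLASSES, TRIAL_MS, AREA_TO_REGION, SpikeDataset
from .hdc import substream

__all__ = ["SynthConfig", "generate", "ground_truth"]

#: Default area assignment: spans visual cortex, hippocampal formation,
#: thalamus, hypothalamus, and midbrain region groups.
DEFAULT_AREAS = ("VISp", "VISal", "VISpm", "CA1", "SUB", "DG", "TH", "ZI", "APN")

_DEFAULT_REPS = {"gabor": 45, "natural_scenes": 50}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic session.

    ``reps_per_class`` / ``n_classes`` default to the full task structure
    (81 x 45 for Gabor, 118 x 50 for scenes); reduced values support
    desk-scale experiments.  ``rf_block_reps`` adds a block of Gabor
    receptive-field-tuning trials to a natural-scenes dataset (the real
    sessions open with such a block), which neuron-level encoding and
    Fano-factor clustering require.
    """

    task: str = "gabor"
    n_areas: int = 3
    units_per_area: int = 10
    frac_inhibitory: float = 0.2
    reps_per_class: int | None = None
    n_classes: int | None = None
    base_rate_hz: float = 10.0
    signal_gain: float = 0.5
    signal_timescale_ms: int = 125
    signal_corr: float = 0.0
    noise_corr: float = 0.2
    inhib_dispersion: float = 3.0
    rf_smoothness: float = 1.0
    rf_block_reps: int = 0
    oscillation_hz: float | None = None
    oscillation_depth: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in N_CLASSES:
            raise ValueError(f"task must be one of {tuple(N_CLASSES)}")
        if not (1 <= self.n_areas <= len(DEFAULT_AREAS)):
            raise ValueError(f"n_areas must lie in [1, {len(DEFAULT_AREAS)}]")
        if TRIAL_MS % self.signal_timescale_ms != 0:
            raise ValueError(f"signal_timescale_ms must divide {TRIAL_MS}")
        if not 0 <= self.noise_corr < 1:
            raise ValueError("noise_corr must lie in [0, 1)")
        if not 0 <= self.signal_corr <= 1:
            raise ValueError("signal_corr must lie in [0, 1]")
        if self.inhib_dispersion < 1:
            raise ValueError("inhib_dispersion must be >= 1")

    @property
    def reps(self) -> int:
        return self.reps_per_class if self.reps_per_class is not None else _DEFAULT_REPS[self.task]

    @property
    def m(self) -> int:
        return self.n_classes if self.n_classes is not None else N_CLASSES[self.task]

    @property
    def n_windows(self) -> int:
        return TRIAL_MS // self.signal_timescale_ms

    @property
    def n_units(self) -> int:
        return self.n_areas * self.units_per_area


def _smooth_grid_field(rng: np.random.Generator, smoothness: float, side: int = 9) -> np.ndarray:
    """A zero-mean, unit-variance random field over the stimulus grid,
    spatially correlated with Gaussian-kernel length scale ``smoothness``."""
    raw = rng.standard_normal((side, side))
    if smoothness <= 0:
        field = raw
    else:
        xs = np.arange(side)
        d2 = (xs[:, None] - xs[None, :]) ** 2.0
        K = np.exp(-d2 / (2.0 * smoothness**2))
        field = K @ raw @ K.T
    field = field - field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def _gabor_rf_fields(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-unit static receptive fields over the 81 grid cells: (units, 81)."""
    fields = np.empty((cfg.n_units, N_CLASSES["gabor"]))
    for i in range(cfg.n_units):
        fields[i] = _smooth_grid_field(rng, cfg.rf_smoothness).ravel()
    return fields


def ground_truth(cfg: SynthConfig) -> dict:
    """Deterministic ground truth underlying :func:`generate`.

    Returns unit areas/regions, true E/I labels, the rate templates
    ``lambda[i, c, w]`` in Hz for the configured task, the static Gabor
    receptive-field templates, and the signal timescale.
    """
    areas = np.repeat(list(DEFAULT_AREAS[: cfg.n_areas]), cfg.units_per_area)
    regions = np.array([AREA_TO_REGION[a] for a in areas])
    n_i = math.ceil(cfg.frac_inhibitory * cfg.units_per_area)
    ei = np.array((["E"] * (cfg.units_per_area - n_i) + ["I"] * n_i) * cfg.n_areas)

    rng_rf = substream(cfg.seed, "synth/rf")
    rf = _gabor_rf_fields(cfg, rng_rf)  # (units, 81), zero-mean unit-variance

    # signal_corr mixes a per-area shared template component into every
    # unit's signal (pairwise within-area signal correlation = signal_corr),
    # so that spatial pooling can genuinely preserve signal while averaging
    # independent noise
    rho = cfg.signal_corr
    area_idx = np.repeat(np.arange(cfg.n_areas), cfg.units_per_area)
    if rho > 0:
        rng_shared = substream(cfg.seed, "synth/templates-shared")
        rf_area = np.stack(
            [_smooth_grid_field(rng_shared, cfg.rf_smoothness).ravel()
             for _ in range(cfg.n_areas)]
        )
        rf = math.sqrt(1 - rho) * rf + math.sqrt(rho) * rf_area[area_idx]

    W = cfg.n_windows
    rng_dyn = substream(cfg.seed, "synth/templates")

    def draw(shape_units):
        ind = rng_dyn.standard_normal((shape_units, cfg.m, W))
        if rho > 0:
            shared = substream(cfg.seed, "synth/dyn-shared").standard_normal(
                (cfg.n_areas, cfg.m, W))
            ind = math.sqrt(1 - rho) * ind + math.sqrt(rho) * shared[area_idx]
        return ind

    if cfg.task == "gabor":
        s = np.repeat(rf[:, : cfg.m, None], W, axis=2).astype(np.float64)
        if W > 1:
            dyn = draw(cfg.n_units)
            s = s + (dyn - dyn.mean(axis=2, keepdims=True))
    else:
        dyn = draw(cfg.n_units)
        if W > 1:
            s = dyn - dyn.mean(axis=2, keepdims=True)
        else:
            s = dyn

    rates = cfg.base_rate_hz * (1.0 + cfg.signal_gain * s)
    clipped = rates < 0
    if clipped.any():
        warnings.warn(
            f"{clipped.mean():.1%} of rate-template entries were negative and clipped to 0; "
            "reduce signal_gain to avoid rectifying the signal"
        )
        rates = np.clip(rates, 0.0, None)

    rf_rates = np.clip(cfg.base_rate_hz * (1.0 + cfg.signal_gain * rf), 0.0, None)
    return {
        "areas": areas,
        "regions": regions,
        "ei_labels": ei,
        "rate_templates_hz": rates,  # (units, m, W)
        "rf_templates_hz": rf_rates,  # (units, 81) static tuning
        "signal_timescale_ms": cfg.signal_timescale_ms,
    }


def _sample_counts(
    rate_1ms: np.ndarray, is_inhib: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Counts for one trial: Poisson rows for E units, negative-binomial
    (matched mean, variance = dispersion * mean) rows for I units."""
    counts = rng.poisson(rate_1ms).astype(np.int32)
    if dispersion > 1 and is_inhib.any():
        mu = rate_1ms[is_inhib]
        r = np.maximum(mu, 1e-12) / (dispersion - 1.0)
        counts[is_inhib] = rng.negative_binomial(r, 1.0 / dispersion)
    return counts


def generate(cfg: SynthConfig) -> SpikeDataset:
    """Draw one synthetic :class:`~spikehd.data.SpikeDataset`.

    Trials of all classes are interleaved in seeded random order.  When
    ``rf_block_reps > 0`` and the task is ``natural_scenes``, a Gabor tuning
    block (all 81 positions, driven by the units' static receptive fields)
    is appended after the scenes trials.
    """
    truth = ground_truth(cfg)
    areas, regions, ei = truth["areas"], truth["regions"], truth["ei_labels"]
    is_inhib = ei == "I"
    units = pd.DataFrame(
        {"unit_id": np.arange(cfg.n_units), "area": areas, "region": regions}
    )

    labels = np.repeat(np.arange(cfg.m), cfg.reps)
    order_rng = substream(cfg.seed, "synth/trial-order")
    labels = labels[order_rng.permutation(labels.size)]
    tasks = [cfg.task] * labels.size
    if cfg.task == "natural_scenes" and cfg.rf_block_reps > 0:
        rf_labels = np.repeat(np.arange(N_CLASSES["gabor"]), cfg.rf_block_reps)
        rf_labels = rf_labels[order_rng.permutation(rf_labels.size)]
        labels = np.concatenate([labels, rf_labels])
        tasks += ["gabor"] * rf_labels.size

    trials = pd.DataFrame(
        {"trial_id": np.arange(labels.size), "task": tasks, "class_label": labels}
    )

    W = cfg.n_windows
    win_of_t = np.arange(TRIAL_MS) // cfg.signal_timescale_ms
    area_of_unit = np.searchsorted(
        np.arange(cfg.n_areas) * cfg.units_per_area, np.arange(cfg.n_units), side="right"
    ) - 1
    sigma = math.sqrt(math.log1p(cfg.noise_corr**2))

    noise_rng = substream(cfg.seed, "synth/noise")
    count_rng = substream(cfg.seed, "synth/counts")
    counts = np.zeros((cfg.n_units, TRIAL_MS, labels.size), dtype=np.int32)
    for k in range(labels.size):
        if tasks[k] == cfg.task:
            lam_w = truth["rate_templates_hz"][:, labels[k], :]  # (units, W)
        else:  # gabor tuning block inside a scenes session: static RF drive
            lam_w = np.repeat(
                truth["rf_templates_hz"][:, labels[k]][:, None], W, axis=1
            )
        if sigma > 0:
            gains = noise_rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=(cfg.n_areas, W))
            lam_w = lam_w * gains[area_of_unit]
        rate_1ms = lam_w[:, win_of_t] / 1000.0  # (units, 250) per-bin mean
        if cfg.oscillation_hz is not None:
            t_global = (k * TRIAL_MS + np.arange(TRIAL_MS)) / 1000.0
            mod = 1.0 + cfg.oscillation_depth * np.sin(2.0 * np.pi * cfg.oscillation_hz * t_global)
            rate_1ms = rate_1ms * mod[None, :]
        counts[:, :, k] = _sample_counts(rate_1ms, is_inhib, cfg.inhib_dispersion, count_rng)
    return SpikeDataset(units, trials, counts)
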