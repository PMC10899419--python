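"""Trial encoding: spike counts -> one hypervector per trial.

Each 250 ms trial of binned multi-unit activity is compressed into a single
D-dimensional trial hypervector through binding and bundling:

1.  **Spatial identity.**  Each spatial unit gets an identity HV ``S_i``.
    At neuron level this is the neuron's receptive-field fingerprint (its
    81-vector of mean spike counts per Gabor position) pushed through a
    random-Fourier-feature map, ``cos(B^T F_i + b) * sin(B^T F_i)``, bound
    with a random HV for the neuron's brain area — so functionally and
    anatomically similar neurons get correlated identities.  Coarser levels
    substitute: population level binds a shared E/I class HV with the area
    HV; area level uses the area HV alone; region level uses one fresh HV
    per region; whole-brain level uses no spatial HV at all.
2.  **Polarization.**  Spiking and silence both carry information: a bin
    with ``n`` spikes contributes ``n * S_i (x) H+``, a silent bin
    contributes ``S_i (x) H-`` with ``H- = -H+``.
3.  **Time.**  Time bin ``t`` of ``M`` gets
    ``T(t) = (1 - t/M) T(0) + (t/M) T(M-1)`` interpolated between two random
    binary endpoint HVs, so nearby bins have similar time HVs.  By default
    the endpoints are drawn independently for every trial, which prevents
    implicit averaging across trials during training; a shared mode reuses
    one endpoint pair everywhere.

The per-bin spatial bundles are bound with their time HVs and bundled over
time into the trial HV.  At whole-brain level this reduces to
``V = sum_t n(t) T(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import N_CLASSES
from .hdc import HDConfig
from .resolution import BinnedTensor

__all__ = [
    "ProjectionBasis",
    "EncoderState",
    "make_projection_basis",
    "encode_receptive_field",
    "build_spatial_hvs",
    "make_time_hvs",
    "encode_trial",
    "encode_trials",
]

TIME_MODES = ("independent_per_trial", "shared")


@dataclass
class ProjectionBasis:
    """Random-Fourier-feature basis for receptive-field encoding.

    ``B`` is an ``(81, D)`` matrix with i.i.d. standard normal entries and
    ``b`` a length-D phase vector uniform on [0, 2*pi); both are regenerated
    deterministically from the master seed.
    """

    B: np.ndarray
    b: np.ndarray


def make_projection_basis(cfg: HDConfig, n_features: int = N_CLASSES["gabor"]) -> ProjectionBasis:
    rng = cfg.rng("projection")
    B = rng.standard_normal((n_features, cfg.D))
    b = rng.uniform(0.0, 2.0 * np.pi, cfg.D)
    return ProjectionBasis(B, b)


def encode_receptive_field(F_i: np.ndarray, basis: ProjectionBasis) -> np.ndarray:
    """Kernel-trick encoding of one receptive-field vector.

    ``cos(B^T F + b) * sin(B^T F)`` element-wise; entries lie in [-1, 1] and
    the similarity of two encodings decays with the distance between their
    feature vectors (an RBF-kernel-like map).  A zero fingerprint encodes to
    the zero vector (sin(0) = 0); such degenerate neurons then contribute
    only through the silence branch of the trial encoding.
    """
    F_i = np.asarray(F_i, dtype=np.float64)
    if F_i.shape != (basis.B.shape[0],):
        raise ValueError(f"receptive-field vector must have length {basis.B.shape[0]}")
    proj = basis.B.T @ F_i
    return np.cos(proj + basis.b) * np.sin(proj)


@dataclass
class EncoderState:
    """All hypervector bases needed to encode trials, derived from one seed.

    Area, region, E/I, polarization, and projection bases are generated
    lazily from named substreams of ``cfg.seed`` and cached, so two states
    with the same config produce bit-identical encodings.
    """

    cfg: HDConfig
    time_mode: str = "independent_per_trial"
    normalize_by_units: bool = False
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.time_mode not in TIME_MODES:
            raise ValueError(f"time_mode must be one of {TIME_MODES}")

    @property
    def basis(self) -> ProjectionBasis:
        if "basis" not in self._cache:
            self._cache["basis"] = make_projection_basis(self.cfg)
        return self._cache["basis"]

    def area_hv(self, area: str) -> np.ndarray:
        """Random HV for one brain area, i.i.d. uniform on [0, 1)."""
        key = ("area", area)
        if key not in self._cache:
            self._cache[key] = self.cfg.rng(f"area/{area}").random(self.cfg.D)
        return self._cache[key]

    def region_hv(self, region: str) -> np.ndarray:
        """Independent random HV for one brain region, uniform on [0, 1)."""
        key = ("region", region)
        if key not in self._cache:
            self._cache[key] = self.cfg.rng(f"region/{region}").random(self.cfg.D)
        return self._cache[key]

    def ei_hv(self, label: str) -> np.ndarray:
        """Bipolar HV for the E or I population class, shared across areas."""
        if label not in ("E", "I"):
            raise ValueError("population label must be 'E' or 'I'")
        key = ("ei", label)
        if key not in self._cache:
            rng = self.cfg.rng(f"population/{label}")
            self._cache[key] = rng.choice((-1.0, 1.0), size=self.cfg.D)
        return self._cache[key]

    @property
    def h_plus(self) -> np.ndarray:
        """Polarization HV for spike presence; absence uses ``-h_plus``."""
        if "h_plus" not in self._cache:
            rng = self.cfg.rng("polarization")
            self._cache["h_plus"] = rng.choice((-1.0, 1.0), size=self.cfg.D)
        return self._cache["h_plus"]

    @property
    def h_minus(self) -> np.ndarray:
        return -self.h_plus

    def time_endpoints(self, trial_key) -> tuple[np.ndarray, np.ndarray]:
        """Binary {0,1} endpoint HVs for a trial's time axis.

        Under ``independent_per_trial`` each trial key gets its own pair;
        under ``shared`` every trial reuses one pair.
        """
        name = "time/shared" if self.time_mode == "shared" else f"time/{trial_key}"
        rng = self.cfg.rng(name)
        endpoints = rng.integers(0, 2, size=(2, self.cfg.D)).astype(np.float64)
        return endpoints[0], endpoints[1]


def build_spatial_hvs(
    state: EncoderState,
    bt: BinnedTensor,
    units: pd.DataFrame | None = None,
    rf_matrix: np.ndarray | None = None,
) -> np.ndarray | None:
    """Identity HVs for the spatial units of a binned tensor.

    Returns an ``(n_spatial_units, D)`` matrix aligned with ``bt.counts``
    rows, or ``None`` at whole-brain level (the whole-brain encoding uses no
    spatial HV).  Neuron level requires the units table and receptive-field
    matrix aligned with the tensor rows; population labels are parsed from
    the tensor's ``"{area}/{E|I}"`` unit labels.
    """
    level = bt.spatial_level
    D = state.cfg.D
    if level == "whole_brain":
        return None
    if level == "neuron":
        if units is None or rf_matrix is None:
            raise ValueError("neuron level requires units table and rf_matrix")
        if len(units) != bt.counts.shape[0] or rf_matrix.shape[0] != bt.counts.shape[0]:
            raise ValueError("units/rf_matrix not aligned with tensor rows")
        S = np.empty((len(units), D))
        areas = units["area"].to_numpy()
        for i in range(len(units)):
            S[i] = encode_receptive_field(rf_matrix[i], state.basis) * state.area_hv(areas[i])
        return S
    if level == "population":
        S = np.empty((len(bt.unit_labels), D))
        for i, label in enumerate(bt.unit_labels):
            area, ei = str(label).rsplit("/", 1)
            S[i] = state.ei_hv(ei) * state.area_hv(area)
        return S
    if level == "area":
        return np.stack([state.area_hv(str(a)) for a in bt.unit_labels])
    if level == "region":
        return np.stack([state.region_hv(str(r)) for r in bt.unit_labels])
    raise ValueError(f"unknown spatial level {level!r}")


def _time_weights(M: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(M, dtype=np.float64)
    return 1.0 - t / M, t / M


def make_time_hvs(M: int, state: EncoderState, trial_key=0) -> np.ndarray:
    """The ``M`` time-bin HVs of one trial as an ``(M, D)`` matrix.

    ``T(t) = (1 - t/M) T(0) + (t/M) T(M-1)`` for ``t = 0..M-1``; the
    interpolated vectors are used as real-valued HVs without re-quantizing.
    Note the printed interpolation uses denominator ``M``, so the final-bin
    HV is close to, but not exactly, its endpoint ``T(M-1)``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    t0, t1 = state.time_endpoints(trial_key)
    w0, w1 = _time_weights(M)
    return np.outer(w0, t0) + np.outer(w1, t1)


def _polar_coeffs(counts_um: np.ndarray, normalize_by_units: bool) -> np.ndarray:
    """Per-(unit, bin) bundling coefficients: n for spiking bins, -1 for silent."""
    c = np.where(counts_um > 0, counts_um.astype(np.float64), -1.0)
    if normalize_by_units:
        pos = counts_um > 0
        c[pos] = c[pos] / counts_um.shape[0]
    return c


def encode_trial(
    counts_um: np.ndarray,
    spatial_hvs: np.ndarray | None,
    state: EncoderState,
    time_hvs: np.ndarray,
) -> np.ndarray:
    """Reference (per-bin loop) encoding of one trial.

    ``counts_um`` is ``(n_spatial_units, M)``; the result is
    ``V = sum_t [ sum_{n_i(t)>0} n_i(t) S_i (x) H+  +  sum_{n_i(t)=0} S_i (x) H- ] (x) T(t)``,
    or ``V = sum_t n(t) T(t)`` when ``spatial_hvs`` is None (whole-brain).
    """
    counts_um = np.asarray(counts_um)
    M = counts_um.shape[1]
    if time_hvs.shape[0] != M:
        raise ValueError("need one time HV per time bin")
    if spatial_hvs is None:
        if counts_um.shape[0] != 1:
            raise ValueError("whole-brain encoding expects a single spatial unit")
        return (counts_um[0].astype(np.float64)[:, None] * time_hvs).sum(axis=0)
    if spatial_hvs.shape[0] != counts_um.shape[0]:
        raise ValueError("one spatial HV per spatial unit required")
    coeffs = _polar_coeffs(counts_um, state.normalize_by_units)
    V = np.zeros(spatial_hvs.shape[1])
    for t in range(M):
        bundle_t = (coeffs[:, t] @ spatial_hvs) * state.h_plus
        V += bundle_t * time_hvs[t]
    return V


def encode_trials(
    bt: BinnedTensor,
    spatial_hvs: np.ndarray | None,
    state: EncoderState,
    trial_keys,
) -> np.ndarray:
    """Encode every trial of a binned tensor; returns ``(n_trials, D)``.

    Algebraically identical to calling :func:`encode_trial` per trial, but
    exploits the linearity of the time interpolation: bundling over time
    collapses onto the two endpoint HVs,
    ``V = (sum_t w0(t) a_t) (x) T(0) + (sum_t w1(t) a_t) (x) T(M-1)``,
    which removes the per-bin loop and makes fine temporal resolutions
    (M = 250) no more expensive than coarse ones.
    """
    n_su, M, n_trials = bt.counts.shape
    if len(trial_keys) != n_trials:
        raise ValueError("need one trial key per trial")
    D = state.cfg.D
    w0, w1 = _time_weights(M)
    out = np.empty((n_trials, D))
    whole_brain = spatial_hvs is None
    if whole_brain and n_su != 1:
        raise ValueError("whole-brain encoding expects a single spatial unit")
    for k in range(n_trials):
        counts_um = bt.counts[:, :, k]
        if whole_brain:
            n_t = counts_um[0].astype(np.float64)
            g0, g1 = float(w0 @ n_t), float(w1 @ n_t)
            a0 = np.full(D, g0)
            a1 = np.full(D, g1)
        else:
            coeffs = _polar_coeffs(counts_um, state.normalize_by_units)  # (n_su, M)
            g0 = coeffs @ w0
            g1 = coeffs @ w1
            a0 = (g0 @ spatial_hvs) * state.h_plus
            a1 = (g1 @ spatial_hvs) * state.h_plus
        t0, t1 = state.time_endpoints(trial_keys[k])
        out[k] = a0 * t0 + a1 * t1
    return out
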