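"""Hypervector generation and algebra.

Hyperdimensional computing (HDC) represents symbols as very high-dimensional
random vectors ("hypervectors", HVs).  At dimension ``D ~ 10**4`` independent
random HVs are nearly orthogonal (the cosine similarity of two independent
Rademacher vectors has standard deviation ``1/sqrt(D)``), which lets simple
component-wise operations act as a reversible symbolic algebra:

* **binding** (component-wise multiplication) associates two HVs; the result
  is nearly orthogonal to both operands, and binding with a bipolar HV is its
  own inverse.
* **bundling** (component-wise addition) superposes HVs; in high dimension
  the sum retains non-negligible similarity to every constituent, so bundling
  memorizes rather than averages.

Permutation (cyclic shift), the third classical HDC operation, is not used
anywhere in this package and is deliberately not provided.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HDConfig",
    "Hypervector",
    "substream",
    "make_bipolar_hv",
    "make_binary_hv",
    "bind",
    "bundle",
    "cosine_similarity",
]

_FLAVORS = ("bipolar", "binary01", "real")


@dataclass(frozen=True)
class HDConfig:
    """Dimension and master seed for all hypervector randomness.

    Every random draw in the package flows deterministically from ``seed``
    through named substreams (see :func:`substream`), so any component can be
    regenerated in isolation.
    """

    D: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.D, (int, np.integer)) or self.D < 2:
            raise ValueError(f"hypervector dimension D must be an integer >= 2, got {self.D}")

    def rng(self, name: str) -> np.random.Generator:
        """Generator for the named substream of this config's master seed."""
        return substream(self.seed, name)


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic, independent random stream identified by ``(seed, name)``.

    The stream name is hashed into the seed sequence entropy so that streams
    for different hypervector families (area HVs, time HVs, ...) are mutually
    independent while each remains reproducible on its own.
    """
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    tag = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


@dataclass
class Hypervector:
    """A dense length-D vector with a flavor constraining admissible values.

    Values are always stored as float64 regardless of flavor; the flavor is
    metadata (``bipolar`` entries lie in {-1,+1}, ``binary01`` in {0,1},
    ``real`` is unconstrained).
    """

    values: np.ndarray
    flavor: str = "real"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("hypervector values must be one-dimensional")
        if self.flavor not in _FLAVORS:
            raise ValueError(f"unknown flavor {self.flavor!r}; expected one of {_FLAVORS}")
        if self.flavor == "bipolar" and not np.all(np.isin(self.values, (-1.0, 1.0))):
            raise ValueError("bipolar hypervector entries must be in {-1, +1}")
        if self.flavor == "binary01" and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise ValueError("binary01 hypervector entries must be in {0, 1}")

    def __len__(self) -> int:
        return self.values.shape[0]

    def __neg__(self) -> "Hypervector":
        flavor = "bipolar" if self.flavor == "bipolar" else "real"
        return Hypervector(-self.values, flavor)


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, Hypervector) else np.asarray(x, dtype=np.float64)


def make_bipolar_hv(cfg: HDConfig, stream: str = "bipolar") -> Hypervector:
    """Draw a Rademacher hypervector: i.i.d. entries uniform over {-1, +1}."""
    rng = cfg.rng(stream)
    return Hypervector(rng.choice((-1.0, 1.0), size=cfg.D), "bipolar")


def make_binary_hv(cfg: HDConfig, stream: str = "binary") -> Hypervector:
    """Draw a binary hypervector: i.i.d. entries uniform over {0, 1}."""
    rng = cfg.rng(stream)
    return Hypervector(rng.integers(0, 2, size=cfg.D).astype(np.float64), "binary01")


def bind(a, b) -> Hypervector:
    """Component-wise product of two hypervectors.

    Binding creates an association: the result is nearly orthogonal to both
    operands, and for a bipolar ``b`` it is self-inverse,
    ``bind(b, bind(b, a)) == a``.
    """
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError(f"dimension mismatch in bind: {va.shape} vs {vb.shape}")
    fa = a.flavor if isinstance(a, Hypervector) else "real"
    fb = b.flavor if isinstance(b, Hypervector) else "real"
    flavor = "bipolar" if fa == fb == "bipolar" else "real"
    return Hypervector(va * vb, flavor)


def bundle(a, b) -> Hypervector:
    """Component-wise sum of two hypervectors (flavor ``real``).

    In high dimension the bundle keeps non-negligible similarity with each
    constituent: for two orthogonal equal-norm HVs the cosine with either
    constituent is 1/sqrt(2), and more generally ~1/sqrt(k) for k of them.
    """
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError(f"dimension mismatch in bundle: {va.shape} vs {vb.shape}")
    return Hypervector(va + vb, "real")


def cosine_similarity(a, b) -> float:
    """Normalized dot product of two equal-length vectors.

    Returns 0.0 when either vector has zero norm.  Class HVs are initialized
    to zero during training, so the first similarity evaluations would
    otherwise be 0/0; an untrained class is treated as maximally
    uninformative.
    """
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError(f"dimension mismatch in cosine_similarity: {va.shape} vs {vb.shape}")
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(va, vb) / (na * nb))
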