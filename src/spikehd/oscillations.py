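"""Regional firing-rate spectra and slowest-oscillation peak estimation.

For each brain region the 1 ms-binned spike counts of its units are averaged
into a population rate, concatenated across all Gabor trials into one
contiguous 1 kHz series (not trial-averaged), and its power spectral density
is estimated with Welch's method.  The spectrum is then parameterized with a
deliberately simple, fully deterministic procedure: the aperiodic (1/f-like)
background is fit as a robust line in log power vs log frequency over
3-50 Hz, subtracted, and local maxima of the residual exceeding a threshold
(a multiple of the robust residual spread) are candidate oscillations.  The
lowest-frequency candidate at or above ``fmin`` (default 3 Hz, below which
the frequency resolution cannot support a peak claim) is reported; if no
candidate qualifies the region has no detected oscillation — an outcome, not
an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data import SpikeDataset
from .evaluation import pearson_randomization_test

__all__ = [
    "RegionRate",
    "SpectralPeak",
    "region_rate",
    "welch_psd",
    "slowest_peak",
    "frequency_resolution_correlation",
]

FS_HZ = 1000.0


@dataclass
class RegionRate:
    """Contiguous 1 kHz mean-rate series (counts/bin) for one region."""

    region: str
    rate: np.ndarray


@dataclass
class SpectralPeak:
    """A detected oscillation: central frequency (Hz), power above the
    aperiodic background (log10 units), and bandwidth (Hz)."""

    central_frequency: float
    power_above_aperiodic: float
    bandwidth: float


def region_rate(ds: SpikeDataset, region: str) -> RegionRate:
    """Mean 1 ms-binned count across a region's units, all Gabor trials
    concatenated in trial-id order: length ``250 * n_gabor_trials``."""
    unit_mask = (ds.units["region"] == region).to_numpy()
    if not unit_mask.any():
        raise ValueError(f"region {region!r} has no units")
    trial_mask = ds.task_mask("gabor")
    if not trial_mask.any():
        raise ValueError("region_rate requires gabor trials")
    order = np.argsort(ds.trials.loc[trial_mask, "trial_id"].to_numpy())
    counts = ds.counts[unit_mask][:, :, trial_mask][:, :, order]
    rate = counts.mean(axis=0).T.reshape(-1)  # trials-major concatenation
    return RegionRate(region, rate)


def welch_psd(
    rate: np.ndarray, window_s: float = 4.0, overlap_frac: float = 0.5, fs: float = FS_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density of a rate series.

    Hann-tapered segments of ``window_s`` seconds with fractional overlap
    ``overlap_frac``; frequency resolution ``1/window_s`` Hz (0.25 Hz at the
    4 s default, enough to resolve theta-band peaks).
    """
    rate = np.asarray(rate, dtype=float)
    nperseg = int(round(window_s * fs))
    if rate.size < nperseg:
        raise ValueError(
            f"rate series ({rate.size} samples) shorter than one {window_s} s window"
        )
    return signal.welch(
        rate, fs=fs, window="hann", nperseg=nperseg, noverlap=int(nperseg * overlap_frac)
    )


def _robust_linefit(x: np.ndarray, y: np.ndarray, n_iter: int = 5) -> tuple[float, float]:
    """Line fit by iteratively reweighted least squares (Huber-like weights),
    so narrow-band peaks do not drag the aperiodic estimate upward."""
    w = np.ones_like(y)
    slope = intercept = 0.0
    for _ in range(n_iter):
        A = np.stack([x, np.ones_like(x)], axis=1) * np.sqrt(w)[:, None]
        slope, intercept = np.linalg.lstsq(A, y * np.sqrt(w), rcond=None)[0]
        resid = y - (slope * x + intercept)
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if scale <= 0:
            break
        z = np.abs(resid) / scale
        w = np.where(z <= 1.345, 1.0, 1.345 / z)
        # one-sided: points far above the line (peaks) are downweighted harder
        w = np.where(resid > 0, w, np.maximum(w, 0.5))
    return slope, intercept


def slowest_peak(
    freqs: np.ndarray,
    power: np.ndarray,
    fmin: float = 3.0,
    fmax: float = 50.0,
    threshold: float = 3.5,
) -> SpectralPeak | None:
    """Lowest-frequency oscillatory peak above the aperiodic background.

    The background is a robust line in log10(power) vs log10(frequency) over
    ``[fmin, fmax]``.  Residual local maxima exceeding ``threshold`` times
    the robust residual spread qualify (the default multiplier is calibrated
    so that pure 1/f spectra yield a detection in well under 10% of runs); the lowest-frequency one at or above
    ``fmin`` is returned, or ``None`` when no peak qualifies.  Bandwidth is
    the frequency span of the contiguous supra-threshold run around the
    peak.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    band = (freqs >= fmin) & (freqs <= fmax) & (power > 0)
    if band.sum() < 8:
        raise ValueError(f"PSD must cover {fmin}-{fmax} Hz with adequate resolution")
    f = freqs[band]
    logf = np.log10(f)
    logp = np.log10(power[band])
    slope, intercept = _robust_linefit(logf, logp)
    resid = logp - (slope * logf + intercept)
    spread = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if spread <= 0:
        return None
    cut = threshold * spread
    above = resid > cut
    peaks, _ = signal.find_peaks(resid, height=cut)
    if peaks.size == 0:
        return None
    pk = peaks[0]  # lowest-frequency qualifying local maximum
    lo = pk
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = pk
    while hi < above.size - 1 and above[hi + 1]:
        hi += 1
    return SpectralPeak(
        central_frequency=float(f[pk]),
        power_above_aperiodic=float(resid[pk]),
        bandwidth=float(f[hi] - f[lo]),
    )


def frequency_resolution_correlation(
    central_freqs, optimal_bin_sizes, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Pearson r (with permutation p) between regions' oscillation central
    frequencies and their optimal temporal bin sizes, paired over
    (subject, region) observations."""
    return pearson_randomization_test(central_freqs, optimal_bin_sizes, n_perm=n_perm, seed=seed)
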