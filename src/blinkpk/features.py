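"""Time- and frequency-domain EMG features for one analysis window.

Two time-domain features are computed on the rectified, normalized window:
the mean amplitude ``v_mean`` and its complement ``v_diff`` = 1 − v_mean
(the difference between the maximum, which is 1 after normalization, and
the mean).

Eleven frequency-domain features are computed on a Welch power spectral
density of the detrended, un-rectified window (rectification distorts the
spectrum, so it is confined to the time-domain branch):

- ``p_mean``, ``p_max``: mean and maximum of the PSD bins;
- ``f_mean``: power-weighted mean frequency Σ(f·P)/ΣP;
- ``p_fmean``: PSD linearly interpolated at f_mean;
- ``f_median``: frequency splitting the spectrum into equal-power halves
  (linear interpolation within the crossing bin);
- ``p_band``: summed power in 30-120 Hz;
- ``p_total``: summed power over all bins;
- ``p_total_over_fmedian``: their ratio;
- ``snr_db``: 10·log10(p_total / (n_bins · median power)) — total power
  against a median-bin noise-floor estimate;
- ``p_bandwidth``: span between the outermost half-power (−3 dB) crossings;
- ``spectral_entropy``: Shannon entropy of the normalized PSD, in bits,
  normalized to [0, 1] by log2(n_bins).

All powers are reported in linear units; only ``snr_db`` is in dB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .preprocess import AnalysisWindow

__all__ = [
    "PsdEstimate",
    "FeatureVector",
    "WelchConfig",
    "welch_psd",
    "time_domain_features",
    "spectral_features",
    "window_features",
    "FEATURE_COLUMNS",
]

#: Feature column order of the exported table.
FEATURE_COLUMNS = (
    "v_mean", "v_diff", "p_mean", "p_max", "f_mean", "p_fmean", "f_median",
    "p_band", "p_total", "p_total_over_fmedian", "snr_db", "p_bandwidth",
    "spectral_entropy",
)


@dataclass(frozen=True)
class PsdEstimate:
    """One-sided PSD on an ascending frequency grid (linear power per bin)."""

    freqs: np.ndarray  # Hz
    power: np.ndarray

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.power):
            raise ValueError("freqs and power must have equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    @property
    def n_bins(self) -> int:
        return len(self.freqs)

    @property
    def resolution_hz(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class FeatureVector:
    window_id: str
    v_mean: float
    v_diff: float
    p_mean: float
    p_max: float
    f_mean: float
    p_fmean: float
    f_median: float
    p_band: float
    p_total: float
    p_total_over_fmedian: float
    snr_db: float
    p_bandwidth: float
    spectral_entropy: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_COLUMNS}


@dataclass(frozen=True)
class WelchConfig:
    """Welch segmentation rule.

    Long windows are split into ``n_segments`` Hamming-windowed segments at
    50% overlap (the segment length is ``floor(2N / (n_segments + 1))``,
    389 samples minus rounding for the 1750-sample T2 window, so the
    averaged periodogram really uses ``n_segments`` segments).  A window too
    short to support that split (fewer than ``min_segment`` samples per
    segment) falls back to a single Hamming-windowed periodogram, zero-padded
    to ``nfft_floor`` — the T1 case (150 samples, nfft 256).
    """

    n_segments: int = 8
    overlap: float = 0.5
    min_segment: int = 128
    nfft_floor: int = 256

    def segmentation(self, n: int) -> tuple[int, int, int]:
        """Return (nperseg, noverlap, nfft) for a window of ``n`` samples."""
        denom = 1.0 + (self.n_segments - 1) * (1.0 - self.overlap)
        nperseg = int(math.floor(n / denom))
        if nperseg < self.min_segment:
            nperseg, noverlap = n, 0
        else:
            noverlap = int(round(nperseg * self.overlap))
        nfft = max(self.nfft_floor, 1 << (nperseg - 1).bit_length())
        return nperseg, noverlap, nfft


def welch_psd(window: AnalysisWindow, cfg: WelchConfig = WelchConfig()) -> PsdEstimate:
    """Welch PSD of a window: Hamming-tapered, 50%-overlapped, averaged.

    Density scaling, so Σ power × resolution equals the window's variance
    (Parseval, within a couple of percent for stationary noise).
    """
    n = len(window.samples)
    nperseg, noverlap, nfft = cfg.segmentation(n)
    if n < nperseg:
        raise ValueError(f"window of {n} samples is shorter than one segment ({nperseg})")
    freqs, power = _signal.welch(
        window.samples, fs=window.fs_hz, window="hamming", nperseg=nperseg,
        noverlap=noverlap, nfft=nfft, detrend=False, scaling="density",
    )
    return PsdEstimate(freqs=freqs, power=power)


def time_domain_features(rectnorm_window: AnalysisWindow,
                         tol: float = 1e-9) -> tuple[float, float]:
    """(v_mean, v_diff) of a rectified, normalized window (max must be 1)."""
    peak = rectnorm_window.samples.max()
    if abs(peak - 1.0) > tol:
        raise ValueError(
            f"window max is {peak!r}, not 1: rectify_normalize must run first"
        )
    v_mean = float(rectnorm_window.samples.mean())
    return v_mean, 1.0 - v_mean


def _interp_crossing(f0: float, f1: float, p0: float, p1: float, level: float) -> float:
    if p1 == p0:
        return f0
    return f0 + (level - p0) * (f1 - f0) / (p1 - p0)


def spectral_features(psd: PsdEstimate,
                      band: tuple[float, float] = (30.0, 120.0)) -> dict[str, float]:
    """The 11 frequency-domain features of one PSD estimate."""
    p = psd.power
    f = psd.freqs
    total = float(p.sum())
    if total <= 0.0:
        raise ValueError("empty spectrum: total power is zero")

    p_mean = float(p.mean())
    p_max = float(p.max())
    f_mean = float((f * p).sum() / total)
    p_fmean = float(np.interp(f_mean, f, p))

    # median frequency: cumulative bin power reaches half the total;
    # linear interpolation inside the crossing bin
    cum = np.cumsum(p)
    target = 0.5 * total
    i = int(np.searchsorted(cum, target))
    if i == 0:
        f_median = float(f[0])
    else:
        f_median = _interp_crossing(f[i - 1], f[i], cum[i - 1], cum[i], target)

    in_band = (f >= band[0]) & (f <= band[1])
    p_band = float(p[in_band].sum())

    med_bin = float(np.median(p))
    snr_db = math.inf if med_bin == 0.0 else 10.0 * math.log10(total / (psd.n_bins * med_bin))

    # outermost half-power crossings
    half = p_max / 2.0
    above = np.nonzero(p >= half)[0]
    lo, hi = int(above[0]), int(above[-1])
    f_lo = float(f[lo]) if lo == 0 else _interp_crossing(
        f[lo - 1], f[lo], p[lo - 1], p[lo], half)
    f_hi = float(f[hi]) if hi == psd.n_bins - 1 else _interp_crossing(
        f[hi + 1], f[hi], p[hi + 1], p[hi], half)
    p_bandwidth = f_hi - f_lo

    q = p / total
    nz = q > 0
    entropy = float(-(q[nz] * np.log2(q[nz])).sum() / np.log2(psd.n_bins))

    return {
        "p_mean": p_mean,
        "p_max": p_max,
        "f_mean": f_mean,
        "p_fmean": p_fmean,
        "f_median": f_median,
        "p_band": p_band,
        "p_total": total,
        "p_total_over_fmedian": total / f_median,
        "snr_db": snr_db,
        "p_bandwidth": p_bandwidth,
        "spectral_entropy": entropy,
    }


def window_features(detrended_window: AnalysisWindow,
                    cfg: WelchConfig = WelchConfig(),
                    band: tuple[float, float] = (30.0, 120.0)) -> FeatureVector:
    """Full 13-feature vector for one detrended (un-rectified) window."""
    from .preprocess import rectify_normalize

    v_mean, v_diff = time_domain_features(rectify_normalize(detrended_window))
    spec = spectral_features(welch_psd(detrended_window, cfg), band=band)
    return FeatureVector(window_id=detrended_window.window_id,
                         v_mean=v_mean, v_diff=v_diff, **spec)
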