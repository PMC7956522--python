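"""ECG conditioning: wavelet denoising, rate conversion, segmentation.

The denoiser decomposes the 125 Hz ECG with an 8-level Daubechies-8 discrete
wavelet transform, zeroes the deepest approximation band (content below about
0.24 Hz — baseline wander) and the first detail band (content above about
31.25 Hz — high-frequency noise), and reconstructs. The reconstruction is
then resampled to 100 Hz, cut into fixed-duration windows, and each ECG
window min–max normalized to [0, 1]. ABP windows are cut time-aligned with
the ECG windows but are never filtered or normalized: blood-pressure targets
are read from them in absolute mmHg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pywt
from scipy.signal import resample_poly

from .errors import ConfigurationError, DecompositionError

__all__ = [
    "WaveletSpec",
    "Segment",
    "dwt_denoise",
    "band_edges",
    "downsample",
    "segment_pair",
    "minmax_normalize",
    "preprocess_record",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Which wavelet bands to discard during denoising.

    ``zeroed_approx`` drops the deepest approximation (the 0..fs/2^(levels+1)
    band); ``zeroed_detail_levels`` lists detail levels to drop, with level 1
    being the finest (fs/4..fs/2).
    """

    mother: str = "db8"
    levels: int = 8
    zeroed_approx: bool = True
    zeroed_detail_levels: frozenset[int] = frozenset({1})

    def validate(self) -> None:
        if self.levels < 1:
            raise ConfigurationError("levels must be >= 1")
        bad = [d for d in self.zeroed_detail_levels if not 1 <= d <= self.levels]
        if bad:
            raise ConfigurationError(f"zeroed detail levels {bad} outside [1, {self.levels}]")


@dataclass
class Segment:
    """One fixed-duration normalized ECG window."""

    samples: np.ndarray
    fs: int
    source_record: int = 0
    start_index: int = 0

    def __len__(self) -> int:
        return len(self.samples)


def dwt_denoise(
    signal: np.ndarray, fs: float, spec: WaveletSpec = WaveletSpec()
) -> np.ndarray:
    """Band-limit ``signal`` by zeroing wavelet bands and reconstructing.

    With no bands zeroed this is the identity (perfect reconstruction of the
    orthogonal DWT). Uses symmetric boundary extension.
    """
    spec.validate()
    x = np.asarray(signal, dtype=float)
    min_len = 2**spec.levels
    if len(x) < min_len:
        raise DecompositionError(
            f"signal of length {len(x)} too short for a {spec.levels}-level "
            f"decomposition (minimum length {min_len})"
        )
    with warnings.catch_warnings():
        # decomposing below pywt's conservative max level is intentional
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, spec.mother, mode="symmetric", level=spec.levels)
    if spec.zeroed_approx:
        coeffs[0] = np.zeros_like(coeffs[0])
    for d in spec.zeroed_detail_levels:
        # wavedec order: [A_L, D_L, D_{L-1}, ..., D_1]
        coeffs[spec.levels - d + 1] = np.zeros_like(coeffs[spec.levels - d + 1])
    rec = pywt.waverec(coeffs, spec.mother, mode="symmetric")
    return rec[: len(x)]


def band_edges(fs: float, spec: WaveletSpec = WaveletSpec()) -> tuple[float, float]:
    """Passband of the denoiser, rounded to 2 decimals.

    The deepest approximation covers 0..(fs/2)/2**levels, the finest detail
    covers fs/4..fs/2, so discarding both leaves ((fs/2)/2**levels, fs/4).
    """
    if fs <= 0:
        raise ConfigurationError("fs must be positive")
    low = (fs / 2.0) / 2.0**spec.levels
    high = (fs / 2.0) / 2.0
    return round(low, 2), round(high, 2)


def downsample(signal: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Rational-ratio polyphase resampling with anti-alias filtering."""
    if fs_out > fs_in:
        raise ConfigurationError(f"fs_out ({fs_out}) must not exceed fs_in ({fs_in})")
    if fs_out == fs_in:
        return np.asarray(signal, dtype=float).copy()
    frac = Fraction(fs_out).limit_denominator(10**6) / Fraction(fs_in).limit_denominator(
        10**6
    )
    return resample_poly(np.asarray(signal, dtype=float), frac.numerator, frac.denominator)


def segment_pair(
    ecg: np.ndarray,
    abp: np.ndarray,
    fs_ecg: float,
    fs_abp: float,
    duration_s: float = 10.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut both signals into time-aligned non-overlapping windows.

    Windows are exactly ``duration_s`` long in each signal's own sampling
    rate; a trailing remainder shorter than one window is discarded.
    """
    n_ecg = int(round(duration_s * fs_ecg))
    n_abp = int(round(duration_s * fs_abp))
    if n_ecg <= 0 or n_abp <= 0:
        raise ConfigurationError("duration_s must span at least one sample")
    n_windows = min(len(ecg) // n_ecg, len(abp) // n_abp)
    return [
        (
            np.asarray(ecg[i * n_ecg : (i + 1) * n_ecg], dtype=float),
            np.asarray(abp[i * n_abp : (i + 1) * n_abp], dtype=float),
        )
        for i in range(n_windows)
    ]


def minmax_normalize(window: np.ndarray) -> np.ndarray:
    """Map a window onto [0, 1]; a constant window maps to all zeros."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ConfigurationError("cannot normalize an empty window")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def preprocess_record(
    record,
    spec: WaveletSpec = WaveletSpec(),
    duration_s: float = 10.0,
    fs_out: float = 100.0,
) -> list[tuple[Segment, np.ndarray]]:
    """Denoise → downsample → segment → normalize one ECG/ABP record.

    Returns time-aligned (normalized ECG segment, raw ABP window) pairs. The
    ABP stays at the recording rate and in mmHg.
    """
    clean = dwt_denoise(record.ecg, record.fs, spec)
    ecg = downsample(clean, record.fs, fs_out)
    pairs = segment_pair(ecg, record.abp, fs_out, record.fs, duration_s)
    n_ecg = int(round(duration_s * fs_out))
    out = []
    for i, (ew, aw) in enumerate(pairs):
        seg = Segment(
            samples=minmax_normalize(ew),
            fs=int(fs_out),
            source_record=getattr(record, "record_id", 0),
            start_index=i * n_ecg,
        )
        out.append((seg, aw))
    return out
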