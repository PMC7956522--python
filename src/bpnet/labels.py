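"""ABP quality gating and ground-truth blood-pressure extraction.

A 10-s ABP window passes quality control only if the sample skewness of
every one of its non-overlapping 1-s sub-windows is non-negative: clean
arterial pulses spend most of each beat near the diastolic floor with a
brief systolic excursion, so their amplitude distribution is right-tailed
(positive skew), while cuff flushes, disconnects and motion artifacts
typically produce a long lower tail (negative skew). Windows that pass
yield targets SBP = max, DBP = min, MAP = (SBP + 2·DBP) / 3, all in mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocess import Segment, WaveletSpec, preprocess_record

__all__ = [
    "BPTargets",
    "LabeledSegment",
    "LabeledDataset",
    "sample_skewness",
    "qc_abp",
    "extract_targets",
    "label_record",
    "build_labeled_arrays",
    "SKEW_FAIL",
]

#: sentinel returned for zero-variance windows; compares below 0, so a
#: flatline ABP window always fails the quality gate
SKEW_FAIL = -np.inf


@dataclass(frozen=True)
class BPTargets:
    """Ground-truth pressures for one window, mmHg."""

    sbp: float
    dbp: float

    @property
    def map(self) -> float:
        """Mean arterial pressure, (SBP + 2·DBP) / 3."""
        return (self.sbp + 2.0 * self.dbp) / 3.0

    def as_array(self) -> np.ndarray:
        return np.array([self.sbp, self.dbp, self.map])

    def __post_init__(self):
        if self.sbp < self.dbp:
            raise ValueError("sbp must be >= dbp")


@dataclass
class LabeledSegment:
    """A normalized ECG segment with its QC verdict and, if passed, targets."""

    ecg: Segment
    qc_passed: bool
    targets: BPTargets | None = None

    def __post_init__(self):
        if self.targets is not None and not self.qc_passed:
            raise ValueError("targets may only be present when qc_passed")


def sample_skewness(window: np.ndarray) -> float:
    """Fisher–Pearson moment skewness g1 = m3 / m2^(3/2).

    Returns the ``SKEW_FAIL`` sentinel (−inf) when the window has zero
    variance, so constant windows always read as quality failures.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 3:
        raise ConfigurationError("skewness needs at least 3 samples")
    d = x - x.mean()
    m2 = np.mean(d * d)
    if m2 == 0.0:
        return SKEW_FAIL
    m3 = np.mean(d * d * d)
    return float(m3 / m2**1.5)


def qc_abp(abp_window: np.ndarray, fs: float) -> bool:
    """True iff no 1-s sub-window of the ABP has negative skewness.

    Sub-windows are consecutive and non-overlapping; a skewness of exactly
    zero passes (the rejection rule is strictly "below zero").
    """
    x = np.asarray(abp_window, dtype=float)
    fs = int(fs)
    if fs <= 0 or len(x) % fs != 0:
        raise ConfigurationError(
            f"ABP window of {len(x)} samples is not an integer number of "
            f"seconds at fs={fs}"
        )
    for i in range(len(x) // fs):
        if sample_skewness(x[i * fs : (i + 1) * fs]) < 0.0:
            return False
    return True


def extract_targets(abp_window: np.ndarray) -> BPTargets:
    """SBP/DBP as the window max/min; MAP follows from them."""
    x = np.asarray(abp_window, dtype=float)
    if x.size == 0:
        raise ConfigurationError("cannot extract targets from an empty window")
    return BPTargets(sbp=float(np.max(x)), dbp=float(np.min(x)))


def label_record(
    record,
    spec: WaveletSpec = WaveletSpec(),
    duration_s: float = 10.0,
    fs_out: float = 100.0,
) -> list[LabeledSegment]:
    """Preprocess one record and attach QC verdicts and targets per window."""
    out = []
    for seg, abp_win in preprocess_record(record, spec, duration_s, fs_out):
        ok = qc_abp(abp_win, record.fs)
        out.append(
            LabeledSegment(
                ecg=seg,
                qc_passed=ok,
                targets=extract_targets(abp_win) if ok else None,
            )
        )
    return out


@dataclass
class LabeledDataset:
    """Matrix form of the QC-passing segments of one split."""

    X: np.ndarray  # (n, segment_len) normalized ECG
    y: np.ndarray  # (n, 3) SBP, DBP, MAP in mmHg
    meta: pd.DataFrame  # record_id, start_index per kept segment

    def __len__(self) -> int:
        return len(self.X)


def build_labeled_arrays(
    records,
    spec: WaveletSpec = WaveletSpec(),
    duration_s: float = 10.0,
    fs_out: float = 100.0,
) -> LabeledDataset:
    """Label every record and stack the QC-passing segments into arrays."""
    xs, ys, rid, start = [], [], [], []
    for rec in records:
        for ls in label_record(rec, spec, duration_s, fs_out):
            if not ls.qc_passed:
                continue
            xs.append(ls.ecg.samples)
            ys.append(ls.targets.as_array())
            rid.append(ls.ecg.source_record)
            start.append(ls.ecg.start_index)
    n_len = int(round(duration_s * fs_out))
    X = np.vstack(xs) if xs else np.empty((0, n_len))
    y = np.vstack(ys) if ys else np.empty((0, 3))
    meta = pd.DataFrame({"record_id": rid, "start_index": start})
    return LabeledDataset(X=X, y=y, meta=meta)
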