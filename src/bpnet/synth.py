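"""Synthetic paired ECG/ABP waveform generator.

Every downstream stage (denoising, quality control, labelling, training,
evaluation) is exercised on data from this module, so the generator encodes
the ground truth explicitly:

* the ABP trace is a quasi-periodic pulse train whose per-beat maximum equals
  the drawn systolic pressure (SBP) and whose per-beat minimum equals the
  drawn diastolic pressure (DBP);
* the ECG is a spike train whose R-wave amplitude encodes SBP and whose
  inter-beat interval encodes DBP, with the strength of that code set by
  ``coupling_strength`` (0 = no blood-pressure information in the ECG,
  1 = a fully deterministic linear code);
* baseline wander (a sinusoid below 0.5 Hz) and high-frequency noise
  (white noise high-passed above 45 Hz) are added to the ECG so the wavelet
  denoiser has something to remove;
* with probability ``artifact_rate`` each 1-s ABP window is replaced by a
  left-skewed disturbance, which is exactly what the skewness quality gate
  is meant to reject.

All randomness derives from ``(seed, record_index)`` so records are
bit-reproducible and independently addressable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError

__all__ = [
    "SimConfig",
    "SignalRecord",
    "SimDataset",
    "generate_record",
    "inject_artifact",
    "make_dataset",
    "save_dataset",
    "load_dataset",
]

# beat geometry: raised-cosine upstroke over the first 30% of the beat,
# exponential relaxation (time constant 15% of the beat) back toward DBP
_UPSTROKE_FRAC = 0.3
_DECAY_FRAC = 0.15
_R_WIDTH_S = 0.02  # Gaussian R-spike standard deviation, seconds


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Pressures are in mmHg, rates in Hz or beats per minute. Defaults give
    ~200 ten-second segments with a fully informative ECG code, clean ABP,
    and mild ECG noise.
    """

    n_records: int = 40
    duration_s: float = 50.0
    fs: int = 125
    sbp_mean: float = 120.0
    sbp_sd: float = 10.0
    dbp_mean: float = 60.0
    dbp_sd: float = 5.0
    heart_rate_range: tuple[float, float] = (60.0, 100.0)
    wander_amplitude: float = 0.15
    wander_freq_hz: float = 0.15
    hf_noise_sd: float = 0.05
    artifact_rate: float = 0.0
    coupling_strength: float = 1.0
    beat_jitter_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_records <= 0:
            raise ConfigurationError("n_records must be positive")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.dbp_mean >= self.sbp_mean:
            raise ConfigurationError("dbp_mean must be below sbp_mean")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigurationError("artifact_rate must lie in [0, 1]")
        if not 0.0 < self.wander_freq_hz < 0.5:
            raise ConfigurationError("wander_freq_hz must lie in (0, 0.5)")
        if self.fs <= 2 * 45:
            raise ConfigurationError("fs must exceed twice the 45 Hz noise band")
        lo, hi = self.heart_rate_range
        if not 0 < lo <= hi:
            raise ConfigurationError("heart_rate_range must be a positive interval")


@dataclass
class SignalRecord:
    """One synchronized ECG/ABP pair with its generating ground truth."""

    ecg: np.ndarray
    abp: np.ndarray
    fs: int
    truth_sbp: np.ndarray  # per-beat systolic pressure, mmHg
    truth_dbp: np.ndarray  # per-beat diastolic pressure, mmHg
    beat_starts: np.ndarray  # sample index of each beat onset
    artifact_windows: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int)
    )  # 1-s window indices corrupted in the ABP
    record_id: int = 0

    def __post_init__(self):
        if len(self.ecg) != len(self.abp):
            raise ValueError("ecg and abp must have equal length")


def _beat_waveform(sbp: float, dbp: float, n: int) -> np.ndarray:
    """One ABP beat of ``n`` samples: min exactly ``dbp``, max exactly ``sbp``."""
    n_up = max(2, int(round(_UPSTROKE_FRAC * n)))
    n_up = min(n_up, n - 1)
    w = np.empty(n)
    k = np.arange(n_up + 1)
    w[: n_up + 1] = dbp + (sbp - dbp) * 0.5 * (1.0 - np.cos(np.pi * k / n_up))
    tail = np.arange(1, n - n_up)
    w[n_up + 1 :] = dbp + (sbp - dbp) * np.exp(-tail / (_DECAY_FRAC * n))
    return w


def _coupled_heart_rate(dbp: float, cfg: SimConfig) -> float:
    """Linear map from diastolic pressure onto the heart-rate interval."""
    lo, hi = cfg.heart_rate_range
    span = 5.0 * max(cfg.dbp_sd, 1e-6)
    u = np.clip((dbp - (cfg.dbp_mean - 2.5 * cfg.dbp_sd)) / span, 0.0, 1.0)
    return lo + (hi - lo) * u


def _highpass_noise(rng: np.random.Generator, n: int, fs: int, sd: float) -> np.ndarray:
    raw = rng.normal(0.0, 1.0, n)
    sos = sps.butter(6, 45.0, btype="highpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, raw)
    s = out.std()
    return out * (sd / s) if s > 0 else out


def _artifact_shape(rng: np.random.Generator, window: np.ndarray) -> np.ndarray:
    """Left-skewed replacement for one 1-s ABP window.

    Mirrors the pulse morphology: most samples sit near the window ceiling
    with sharp excursions downward, giving a long lower tail and strictly
    negative sample skewness.
    """
    n = len(window)
    top = float(np.max(window))
    depth = max(float(np.ptp(window)), 20.0)
    period = max(8, n // 5)
    k = np.arange(n)
    dip = np.exp(-(k % period) / (0.25 * period))
    out = top - depth * dip + rng.normal(0.0, 0.005 * depth, n)
    return out


def generate_record(cfg: SimConfig, record_index: int) -> SignalRecord:
    """Deterministically generate record ``record_index`` of the cohort."""
    cfg.validate()
    if not 0 <= record_index < cfg.n_records:
        raise ConfigurationError(
            f"record_index {record_index} out of range for n_records={cfg.n_records}"
        )
    rng = np.random.default_rng([cfg.seed, 1, record_index])
    n = int(round(cfg.duration_s * cfg.fs))

    # record-level pressures; redraw until physiologically ordered
    for _ in range(100):
        sbp0 = rng.normal(cfg.sbp_mean, cfg.sbp_sd)
        dbp0 = rng.normal(cfg.dbp_mean, cfg.dbp_sd)
        if sbp0 - dbp0 >= 20.0:
            break
    else:  # pragma: no cover - essentially impossible at sane configs
        sbp0, dbp0 = cfg.sbp_mean, cfg.dbp_mean
    hr_free = rng.uniform(*cfg.heart_rate_range)

    c = cfg.coupling_strength
    abp_parts: list[np.ndarray] = []
    beat_starts: list[int] = []
    sbps: list[float] = []
    dbps: list[float] = []
    amps: list[float] = []
    total = 0
    while total < n:
        sbp_b = sbp0 + rng.normal(0.0, cfg.beat_jitter_sd)
        dbp_b = dbp0 + rng.normal(0.0, cfg.beat_jitter_sd)
        if sbp_b - dbp_b < 10.0:
            sbp_b = dbp_b + 10.0
        hr_b = c * _coupled_heart_rate(dbp_b, cfg) + (1.0 - c) * (
            hr_free + rng.normal(0.0, 2.0)
        )
        hr_b = float(np.clip(hr_b, 30.0, 200.0))
        period = max(8, int(round(cfg.fs * 60.0 / hr_b)))
        # R amplitude: linear code of systolic pressure when coupled,
        # free variation otherwise
        amp_b = 1.0 + c * (sbp_b - cfg.sbp_mean) / (4.0 * max(cfg.sbp_sd, 1.0)) + (
            1.0 - c
        ) * rng.normal(0.0, 0.1)
        beat_starts.append(total)
        sbps.append(sbp_b)
        dbps.append(dbp_b)
        amps.append(amp_b)
        abp_parts.append(_beat_waveform(sbp_b, dbp_b, period))
        total += period
    abp = np.concatenate(abp_parts)[:n]

    # ECG: Gaussian R spikes at beat onsets + wander + high-passed noise
    t = np.arange(n) / cfg.fs
    ecg = np.zeros(n)
    half = int(round(4 * _R_WIDTH_S * cfg.fs))
    for start, amp in zip(beat_starts, amps):
        center = start + int(round(0.1 * cfg.fs))
        lo, hi = max(0, center - half), min(n, center + half + 1)
        if lo >= hi:
            continue
        tt = (np.arange(lo, hi) - center) / cfg.fs
        ecg[lo:hi] += amp * np.exp(-0.5 * (tt / _R_WIDTH_S) ** 2)
    if cfg.wander_amplitude > 0:
        ecg += cfg.wander_amplitude * np.sin(
            2 * np.pi * cfg.wander_freq_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if cfg.hf_noise_sd > 0:
        ecg += _highpass_noise(rng, n, cfg.fs, cfg.hf_noise_sd)

    # ABP artifacts: independent per 1-s window
    artifact_windows: list[int] = []
    if cfg.artifact_rate > 0:
        n_windows = n // cfg.fs
        hits = rng.random(n_windows) < cfg.artifact_rate
        for w in np.flatnonzero(hits):
            seg = slice(w * cfg.fs, (w + 1) * cfg.fs)
            abp[seg] = _artifact_shape(rng, abp[seg])
            artifact_windows.append(int(w))

    return SignalRecord(
        ecg=ecg,
        abp=abp,
        fs=cfg.fs,
        truth_sbp=np.asarray(sbps),
        truth_dbp=np.asarray(dbps),
        beat_starts=np.asarray(beat_starts, dtype=int),
        artifact_windows=np.asarray(artifact_windows, dtype=int),
        record_id=record_index,
    )


def inject_artifact(record: SignalRecord, window_index: int, seed: int) -> SignalRecord:
    """Return a copy of ``record`` with one 1-s ABP window replaced by a
    negative-skew disturbance; every other sample is untouched."""
    n_windows = len(record.abp) // record.fs
    if not 0 <= window_index < n_windows:
        raise IndexError(
            f"window_index {window_index} out of range (record has {n_windows} 1-s windows)"
        )
    rng = np.random.default_rng([seed, 2, window_index])
    abp = record.abp.copy()
    seg = slice(window_index * record.fs, (window_index + 1) * record.fs)
    abp[seg] = _artifact_shape(rng, abp[seg])
    marks = np.union1d(record.artifact_windows, [window_index]).astype(int)
    return replace(record, abp=abp, artifact_windows=marks)


@dataclass
class SimDataset:
    """A generated cohort plus its train/validation/test manifest."""

    records: list[SignalRecord]
    manifest: pd.DataFrame  # columns: record_id, split, sbp, dbp
    config: SimConfig

    def split(self, name: str) -> list[SignalRecord]:
        ids = set(self.manifest.loc[self.manifest["split"] == name, "record_id"])
        return [r for r in self.records if r.record_id in ids]


def _split_labels(n: int, rng: np.random.Generator) -> np.ndarray:
    n_val = int(round(0.1 * n))
    n_test = int(round(0.1 * n))
    labels = np.array(
        ["train"] * (n - n_val - n_test) + ["val"] * n_val + ["test"] * n_test
    )
    rng.shuffle(labels)
    return labels


def make_dataset(cfg: SimConfig) -> SimDataset:
    """Generate the full cohort and split it 80/10/10 by record."""
    cfg.validate()
    if cfg.n_records < 10:
        raise ConfigurationError(
            "n_records must be at least 10 to realize the 80/10/10 split"
        )
    records = [generate_record(cfg, i) for i in range(cfg.n_records)]
    labels = _split_labels(cfg.n_records, np.random.default_rng([cfg.seed, 3]))
    manifest = pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "split": labels,
            "sbp": [float(np.mean(r.truth_sbp)) for r in records],
            "dbp": [float(np.mean(r.truth_dbp)) for r in records],
        }
    )
    return SimDataset(records=records, manifest=manifest, config=cfg)


def save_dataset(ds: SimDataset, outdir) -> None:
    """Write one NPZ per record plus a CSV manifest."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for r in ds.records:
        np.savez(
            out / f"record_{r.record_id:04d}.npz",
            ecg=r.ecg,
            abp=r.abp,
            fs=r.fs,
            truth_sbp=r.truth_sbp,
            truth_dbp=r.truth_dbp,
            beat_starts=r.beat_starts,
            artifact_windows=r.artifact_windows,
        )
    ds.manifest.to_csv(out / "manifest.csv", index=False)


def load_dataset(indir, cfg: SimConfig | None = None) -> SimDataset:
    from pathlib import Path

    ind = Path(indir)
    manifest = pd.read_csv(ind / "manifest.csv")
    records = []
    for rid in manifest["record_id"]:
        z = np.load(ind / f"record_{rid:04d}.npz")
        records.append(
            SignalRecord(
                ecg=z["ecg"],
                abp=z["abp"],
                fs=int(z["fs"]),
                truth_sbp=z["truth_sbp"],
                truth_dbp=z["truth_dbp"],
                beat_starts=z["beat_starts"],
                artifact_windows=z["artifact_windows"],
                record_id=int(rid),
            )
        )
    return SimDataset(records=records, manifest=manifest, config=cfg or SimConfig())
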