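"""Wavelet denoising: remove baseline wander and high-frequency noise.

An 8-level db8 decomposition of a 125 Hz ECG isolates baseline wander in
the deepest approximation (below ~0.24 Hz) and broadband noise in the first
detail band (above ~31.25 Hz); zeroing both and reconstructing band-limits
the signal, after which it is resampled to 100 Hz.
"""

import numpy as np

from bpnet import SimConfig, WaveletSpec, band_edges, downsample, dwt_denoise, generate_record

spec = WaveletSpec()
low, high = band_edges(125.0, spec)
print(f"denoiser passband: {low} Hz to {high} Hz")

rec = generate_record(
    SimConfig(n_records=1, duration_s=10.0, wander_amplitude=0.4, hf_noise_sd=0.2,
              wander_freq_hz=0.1, seed=2), 0)
clean = dwt_denoise(rec.ecg, rec.fs, spec)


def band_power(x, fs, lo, hi):
    spectrum = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1 / fs)
    return spectrum[(freqs >= lo) & (freqs < hi)].sum()


for name, lo, hi in [("wander band (<0.24 Hz)", 0.0, 0.24),
                     ("noise band (>45 Hz)", 45.0, 62.5)]:
    before = band_power(rec.ecg, rec.fs, lo, hi)
    after = band_power(clean, rec.fs, lo, hi)
    print(f"{name}: {100 * after / before:.2f}% of the power survives")

resampled = downsample(clean, 125, 100)
print(f"resampled {len(clean)} samples at 125 Hz -> {len(resampled)} at 100 Hz")
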