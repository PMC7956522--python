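# Methods

This note documents the models and procedures implemented in `bpnet`, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not demonstrate.

## Signal model and preprocessing

The input is a pair of synchronized waveforms sampled at 125 Hz: a
single-lead ECG (arbitrary amplitude units) and an invasive arterial blood
pressure (ABP) trace in mmHg.

**Wavelet denoising.** The ECG is decomposed with an 8-level discrete
wavelet transform using the Daubechies-8 mother wavelet and symmetric
(half-sample) boundary extension. In the dyadic band picture the deepest
approximation covers 0 to (fs/2)/2⁸ = 0.244 Hz and the finest detail band
covers fs/4 to fs/2 = 31.25–62.5 Hz. Zeroing both coefficient sets and
reconstructing removes baseline wander and high-frequency noise while
passing 0.24–31.25 Hz. Two consequences are accepted deliberately:

* the scheme's upper edge (31.25 Hz) is below the commonly cited useful
  ECG band top of 45 Hz — the scheme is implemented exactly as specified
  rather than "fixed", since the discarded detail band cannot be split;
* at 10-s windows (1250 samples) the deepest levels have very few
  coefficients; the transform is still perfectly invertible (verified to
  1e−8 relative error with no bands zeroed), and the measured stopband
  retention on a 0.1 Hz test sinusoid is below 1%.

The minimum accepted signal length is 2⁸ samples; shorter inputs raise an
error naming that bound.

**Resampling.** 125 → 100 Hz is the exact rational ratio 4/5 and is done
by polyphase resampling with the default Kaiser anti-alias filter. The
denoised signal is already band-limited to 31.25 Hz < 50 Hz, so no
aliasing is introduced. The anti-alias filter has ~0.5% passband ripple,
which is irrelevant after min–max normalization.

**Segmentation and normalization.** Non-overlapping 10-s windows, cut
time-aligned in each signal's own rate (1000 ECG samples at 100 Hz, 1250
ABP samples at 125 Hz); a trailing remainder is discarded. Each ECG window
is min–max normalized to [0, 1]; a constant window maps to zeros (such
windows are physiologically dead). ABP windows are never normalized —
targets are read in absolute mmHg.

## Quality control and targets

Sample skewness is the population Fisher–Pearson moment coefficient
g1 = m3/m2^{3/2}. At 125 samples per 1-s window the small-sample
correction would change g1 by under 2% and is omitted, matching the usual
signal-quality-index convention. A zero-variance window returns a −∞
sentinel, so flatlines always fail. A 10-s ABP window is rejected iff any
of its ten non-overlapping 1-s sub-windows has skewness strictly below
zero (exactly zero passes). Passing windows yield SBP = max, DBP = min
over the whole window (not per-beat averages), and
MAP = (SBP + 2·DBP)/3 — an identity that holds exactly for every emitted
target.

## Network

A 1000-sample segment is folded into 20 contiguous steps of 50 samples.
The trunk is a 2-layer bidirectional LSTM (hidden size H per direction;
the second layer consumes the concatenated 2H-wide outputs of the first).
The readout concatenates the last layer's final forward state and final
backward state (2H wide). Each task head is affine(2H→2H)+ReLU,
affine(2H→H)+ReLU, affine(H→1); heads are architecturally identical but
independently parameterized. The scalar readout layer is the minimal
regression head for mmHg targets, which are regressed raw (no target
standardization).

All weights and biases are initialized from U(−1/√H, 1/√H) excluding
exact zeros — the standard recurrent-layer scaling that keeps initial
values small. The trunk/readout/heads are implemented in NumPy with
analytic backpropagation; gradients are verified against central finite
differences to 1e−4 relative error on a down-scaled configuration, which
is the expected finite-difference noise floor at this loss magnitude.

Two scales are provided: the reference configuration (H = 256, heads
512/256) and a desk scale for CPU-only runs (H = 64, heads 128/64,
preserving the invariant that the first head width equals the 2H trunk
output width).

## Training and adaptive task weighting

Optimization is mini-batch SGD with momentum 0.9, learning rate 8·10⁻⁴,
batch size 128, and an explicit L2 penalty (wd/2)·Σ‖p‖² with factor
wd = 0.1 over all weights and biases (gradient contribution wd·p). The
learning rate is multiplied by 0.9 when the epoch training loss (data term
plus penalty) has not improved for more than 4 consecutive epochs. The
per-task training loss is the batch RMSE; validation statistics use the
batch MAE — both as stated for the method, selectable via `loss_kind`.

Task weights θ = (θ_s, θ_d, θ_m) start at 1/3 each. After every epoch
k > 0 the validation set is split into M ≥ 2 fixed batches; per task the
mean L_mean and population standard deviation L_std of the M batch MAEs
are computed, and their relative trends
T = (L(k) − L(k−1)) / max(L(k), 1e−12). The raw importance is
r_i = |T_mean,i · T_std,i| · (L_mean,i + L_std,i), normalized to
θ_i = r_i / Σ r. Design choices here:

* the absolute value of the trend product — mixed-sign trends would
  otherwise break the normalization of what is semantically an importance;
* raw-then-normalize (no blending with the previous epoch's θ);
* uniform fallback when Σ r < 1e−12, e.g. for a frozen model;
* all divisions epsilon-guarded at 1e−12.

Ablation modes reuse identical code paths: `uniform_weights=True` fixes
every task weight at 1 (the unweighted joint-training baseline), and a
single-task configuration keeps the same trunk with one head. Data
shuffling is reseeded per epoch from the run seed, so a full run is
bit-reproducible given seed, config and data.

Divergence (non-finite loss or parameters) aborts with an error carrying
the last completed epoch's parameters.

## Evaluation

MErr = mean(y − ŷ), MAErr = mean|y − ŷ|, RMSErr = √mean((y − ŷ)²); these
satisfy RMSErr ≥ MAErr ≥ |MErr| on any sample. Cumulative percentages
count |y − ŷ| ≤ 5/10/15 mmHg (boundary inclusive, the common reading of
"within"). BHS grading applies the A/B/C thresholds inclusively and
returns the best satisfied grade; it is monotone in every CP entry. The
AAMI verdict defaults to the reported rule |MErr| ≤ 5 and MAErr ≤ 8 mmHg;
a strict mode implementing the standard's mean ± SD criterion
(|MErr| ≤ 5, SD ≤ 8) is provided because the two differ. Bland–Altman
differences are estimated minus truth with limits mean ± 1.96 × sample
(n−1) SD; the variant export replaces the pair-mean x axis with the
ground-truth value, which makes the vertical stripes at common pressures
visible.

## Synthetic data generator

The generator stands in for clinical waveform archives and encodes a known
ground truth:

* **ABP**: per record, record-level SBP/DBP are drawn from
  N(120, 10²)/N(60, 5²) mmHg (redrawn until separated by ≥ 20 mmHg); per
  beat, small N(0, 1²) jitter is added. Each beat is a raised-cosine
  upstroke over the first 30% of the period followed by exponential
  relaxation (time constant 15% of the period), so the sampled minimum is
  exactly the drawn DBP and the maximum exactly the drawn SBP, and every
  1-s window of clean signal has positive skewness.
* **ECG**: Gaussian R spikes (σ = 20 ms) at each beat onset. With coupling
  strength c, the R amplitude varies linearly with the beat's SBP and the
  heart rate maps linearly from the beat's DBP into the configured
  60–100 bpm range; at c = 0 both vary freely, so the ECG carries no
  pressure information (cohort correlation indistinguishable from zero at
  n = 200), while at c = 1 the code is fully deterministic (correlation
  > 0.99). Baseline wander is a sinusoid (default 0.15 Hz, inside the
  denoiser's stopband) and high-frequency noise is white noise high-passed
  above 45 Hz.
* **Artifacts**: with probability `artifact_rate` per 1-s window, the ABP
  window is replaced by a left-skewed disturbance (samples near the window
  ceiling with sharp downward excursions), which the skewness gate
  rejects; the segment discard rate therefore follows 1 − (1 − r)¹⁰.
* **Reproducibility**: each record's stream derives from (seed, index), so
  records are independently addressable and bitwise reproducible; the
  80/10/10 record-level split is drawn from its own seeded stream and
  requires at least 10 records.

What the generator does **not** emulate: realistic ECG morphology (P/T
waves, QRS shape variability, arrhythmia), hemodynamic coupling beyond a
linear code, inter-patient variability structure, sensor drift, or the
signal statistics of intensive-care archives. Passing tests therefore
demonstrate that the pipeline recovers a learnable morphology-to-pressure
code and that every stage honors its contracts — not clinical-grade
accuracy on real patients.

## Problem sizes and runtime choices

The bundled study conditions use 40 records × 50 s (≈ 200 ten-second
segments, 160/20/20 after the split), the desk-scale network (H = 64) and
30 epochs; this trains in seconds on one CPU while exhibiting the
mechanics of interest (decreasing validation MAE for all three tasks,
non-trivial weight trajectories). With mmHg-scale targets and the
prescribed small learning rate, 30 epochs reduce the validation MAE
steadily but by design remain far from convergence — the reference
schedule is 500 epochs at H = 256. The pipeline's orchestration recomputes
every stage per run into a directory named by the configuration hash, so
outputs of different configurations can never be silently mixed.

## Known limitations

* No dropout between trunk layers (unspecified in the method; none used).
* The fold of 1000 samples into 20 × 50 is one of two defensible readings
  of the sequence geometry; both satisfy 20 × 50 = 1000 and the choice is
  configurable via `seq_len`/`step_dim`.
* The L2 factor 0.1 is implemented as an explicit additive penalty; under
  momentum this differs slightly from optimizer-coupled weight decay.
* CSV/NPZ are the supported interchange formats; clinical waveform-archive
  readers are out of scope.
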