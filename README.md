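# bpnet

Calibration-free continuous blood-pressure estimation from single-lead ECG
with an adaptively weighted multitask BiLSTM.

## The problem

Cuff sphygmomanometers give point measurements and are impractical for
long-term monitoring, while wearable devices can record a single-lead ECG
continuously. Because R-wave morphology reflects the intensity of
ventricular contraction and hence cardiac ejection, the ECG carries
information about arterial pressure. `bpnet` implements an end-to-end
regression pipeline from 10-s ECG segments to the three standard pressure
indices — systolic (SBP), diastolic (DBP) and mean arterial pressure
(MAP = (SBP + 2·DBP)/3) — with ground truth extracted from synchronized
invasive arterial blood pressure (ABP) waveforms.

The pipeline:

1. **Denoising** — 8-level Daubechies-8 discrete wavelet transform of the
   125 Hz ECG; the deepest approximation band (0–0.24 Hz, baseline wander)
   and the finest detail band (31.25–62.5 Hz, high-frequency noise) are
   zeroed before reconstruction; the result is resampled to 100 Hz.
2. **Segmentation** — non-overlapping 10-s windows, each ECG window
   min–max normalized to [0, 1]; ABP windows stay raw, in mmHg.
3. **Quality control and labels** — a 10-s ABP window is discarded if the
   sample skewness of any of its 1-s sub-windows is negative (clean
   arterial pulses are right-skewed; artifacts have long lower tails).
   Passing windows yield Y_s = max, Y_d = min, Y_m = (Y_s + 2·Y_d)/3.
4. **Model** — a shared 2-layer bidirectional LSTM trunk reads the segment
   as 20 steps × 50 samples; the final forward and backward hidden states
   are concatenated (width 2H) and feed three identical, independently
   parameterized fully connected heads (2H→512→256→1 with ReLU at the
   default hidden size 256), giving Ŷ_s, Ŷ_d, Ŷ_m in mmHg.
5. **Adaptive multitask training** — the joint loss is
   L_total = Σ_i θ_i·L_i with per-task batch RMSE, trained by momentum SGD
   (lr 8·10⁻⁴, momentum 0.9, batch 128, L2 factor 0.1, plateau decay ×0.9
   with patience 4). The weights θ_i start at 1/3 and from the second
   epoch are re-derived from validation statistics: with L_mean, L_std the
   mean/std of per-batch validation MAE and T_mean, T_std their relative
   epoch-over-epoch trends, θ_i ∝ |T_mean,i·T_std,i|·(L_mean,i + L_std,i),
   normalized to sum to 1. Tasks whose loss is large and still moving
   attract more gradient.
6. **Evaluation** — MErr/MAErr/RMSErr, cumulative percentages of absolute
   errors within 5/10/15 mmHg, British Hypertension Society grade, AAMI
   verdict, and classic + variant Bland–Altman exports.

Everything, including the network and its backpropagation, is implemented
in NumPy. A bundled synthetic ECG/ABP generator (`bpnet.synth`) encodes
known pressures into waveform morphology so the whole pipeline is testable
end to end without clinical data.

## Worked example

```python
from bpnet import ModelConfig, SimConfig, TrainConfig, make_dataset, train
from bpnet.labels import build_labeled_arrays

dataset = make_dataset(SimConfig(n_records=40, duration_s=50.0, seed=11))
splits = {name: build_labeled_arrays(dataset.split(name))
          for name in ("train", "val")}
result = train(splits["train"], splits["val"],
               ModelConfig.desk_scale(), TrainConfig(max_epochs=10, seed=5))
print(result.log[["epoch", "theta_sbp", "theta_dbp", "theta_map",
                  "val_mean_sbp"]].head(3).to_string(index=False))
```

prints

```
 epoch  theta_sbp  theta_dbp  theta_map  val_mean_sbp
     0   0.333333   0.333333   0.333333    123.774850
     1   0.241122   0.452473   0.306404    123.774067
     2   0.166899   0.403172   0.429929    123.773068
```

Epoch 0 trains with the uniform weights 1/3; afterwards the weights track
each task's validation-loss trend while remaining a convex combination.
`val_mean_sbp` is the SBP validation MAE in mmHg, which decreases as
training proceeds. The `examples/` directory has one short script per
capability (simulation, denoising, quality gating, training, agreement
evaluation); `bpnet run --out DIR` executes the whole pipeline from the
command line, and `bpnet simulate/label/evaluate` expose the stages.

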