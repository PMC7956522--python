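"""Skewness quality gate and ground-truth extraction.

Clean arterial pulses are right-skewed (most samples near the diastolic
floor); artifacts with a long lower tail are left-skewed. Any 1-s window
with negative skewness discards the whole 10-s segment. Passing windows
yield SBP = max, DBP = min, MAP = (SBP + 2 DBP) / 3.
"""

from bpnet import SimConfig, extract_targets, generate_record, inject_artifact, qc_abp, sample_skewness

rec = generate_record(SimConfig(n_records=1, duration_s=10.0, seed=4), 0)
print("clean segment passes QC:", qc_abp(rec.abp, rec.fs))

skews = [sample_skewness(rec.abp[i * rec.fs:(i + 1) * rec.fs]) for i in range(10)]
print("per-second skewness:", " ".join(f"{s:.2f}" for s in skews))

targets = extract_targets(rec.abp)
print(f"targets: SBP {targets.sbp:.1f}  DBP {targets.dbp:.1f}  "
      f"MAP {targets.map:.1f} mmHg")

bad = inject_artifact(rec, window_index=6, seed=0)
print("after injecting a left-skewed artifact in second 6:")
print("  skewness there:", f"{sample_skewness(bad.abp[6 * rec.fs:7 * rec.fs]):.2f}")
print("  segment passes QC:", qc_abp(bad.abp, bad.fs))
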