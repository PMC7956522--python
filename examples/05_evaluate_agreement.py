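"""Agreement evaluation: error metrics, BHS grade, AAMI verdict, Bland–Altman.

Evaluates a mock estimator (truth plus noise of realistic magnitude) to show
the full report; in practice the predictions come from the trained network
(see the pipeline in `bpnet.run_all`).
"""

import numpy as np

from bpnet import bland_altman, evaluate_predictions

rng = np.random.default_rng(0)
n = 2000
truth = np.column_stack([rng.normal(120, 12, n), rng.normal(60, 6, n)])
truth = np.column_stack([truth, (truth[:, 0] + 2 * truth[:, 1]) / 3])
pred = truth + rng.normal(0, [5.5, 3.0, 3.5], truth.shape)

report = evaluate_predictions(truth, pred)
for task, rep in report.tasks.items():
    m, cp = rep.metrics, rep.cp
    print(f"{task}: MErr {m.merr:+.2f}  MAErr {m.maerr:.2f}  RMSErr {m.rmserr:.2f} mmHg | "
          f"CP5/10/15 {cp.cp5:.1f}/{cp.cp10:.1f}/{cp.cp15:.1f}% | "
          f"BHS {rep.bhs} | AAMI {'pass' if rep.aami_pass else 'fail'}")

stats, export = bland_altman(truth[:, 0], pred[:, 0])
print(f"SBP Bland–Altman: mean diff {stats.mean_diff:+.2f} mmHg, "
      f"limits [{stats.lower_loa:.2f}, {stats.upper_loa:.2f}] "
      f"(mean ± 1.96·SD, SD {stats.sd_diff:.2f})")
print(f"export table has {len(export)} (pair-mean, difference) rows for plotting")
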