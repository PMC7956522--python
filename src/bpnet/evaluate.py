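"""Agreement evaluation: error metrics, BHS grade, AAMI verdict, Bland–Altman.

Conventions
-----------
* Errors are reported as MErr = mean(y − ŷ) (signed), MAErr = mean|y − ŷ|,
  RMSErr = √mean((y − ŷ)²), all in mmHg.
* The cumulative-percentage table counts absolute errors lying within (≤)
  5, 10 and 15 mmHg; the British Hypertension Society thresholds are
  applied inclusively, and the best satisfied grade is returned.
* The AAMI verdict defaults to the "reported" rule |MErr| ≤ 5 and
  MAErr ≤ 8 mmHg; ``mode="strict"`` applies the standard's own criterion
  |mean error| ≤ 5 and error SD ≤ 8 mmHg.
* Bland–Altman differences are estimated minus ground truth, with limits of
  agreement mean ± 1.96 × sample SD; the variant export uses the ground
  truth (rather than the pair mean) as its x coordinate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "ErrorMetrics",
    "CPTable",
    "BlandAltmanStats",
    "EvalReport",
    "error_metrics",
    "cumulative_percentages",
    "bhs_grade",
    "aami_check",
    "bland_altman",
    "variant_bland_altman",
    "evaluate_task",
    "evaluate_predictions",
]

#: BHS grade → (cp5, cp10, cp15) minima, percent
BHS_THRESHOLDS = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}


@dataclass(frozen=True)
class ErrorMetrics:
    merr: float
    maerr: float
    rmserr: float
    n: int


@dataclass(frozen=True)
class CPTable:
    cp5: float
    cp10: float
    cp15: float


@dataclass(frozen=True)
class BlandAltmanStats:
    mean_diff: float
    sd_diff: float
    lower_loa: float
    upper_loa: float


def _check_pair(truth, pred, min_n=1):
    y = np.asarray(truth, dtype=float)
    yh = np.asarray(pred, dtype=float)
    if y.shape != yh.shape or y.ndim != 1:
        raise ConfigurationError("truth and pred must be equal-length 1-D arrays")
    if len(y) < min_n:
        raise ConfigurationError(f"need at least {min_n} paired values")
    return y, yh


def error_metrics(truth, pred) -> ErrorMetrics:
    y, yh = _check_pair(truth, pred)
    e = y - yh
    return ErrorMetrics(
        merr=float(np.mean(e)),
        maerr=float(np.mean(np.abs(e))),
        rmserr=float(np.sqrt(np.mean(e**2))),
        n=len(y),
    )


def cumulative_percentages(truth, pred) -> CPTable:
    y, yh = _check_pair(truth, pred)
    ae = np.abs(y - yh)
    return CPTable(
        cp5=float(np.mean(ae <= 5.0) * 100.0),
        cp10=float(np.mean(ae <= 10.0) * 100.0),
        cp15=float(np.mean(ae <= 15.0) * 100.0),
    )


def bhs_grade(cp: CPTable) -> str:
    for grade in ("A", "B", "C"):
        t5, t10, t15 = BHS_THRESHOLDS[grade]
        if cp.cp5 >= t5 and cp.cp10 >= t10 and cp.cp15 >= t15:
            return grade
    return "fail"


def aami_check(metrics: ErrorMetrics, mode: str = "reported", sd: float | None = None) -> bool:
    """AAMI verdict.

    ``mode="reported"`` — pass iff |MErr| ≤ 5 mmHg and MAErr ≤ 8 mmHg.
    ``mode="strict"`` — pass iff |MErr| ≤ 5 mmHg and the error SD ≤ 8 mmHg
    (requires ``sd``, e.g. from :func:`bland_altman`).
    """
    if mode == "reported":
        return abs(metrics.merr) <= 5.0 and metrics.maerr <= 8.0
    if mode == "strict":
        if sd is None:
            raise ConfigurationError("strict AAMI mode needs the error SD")
        return abs(metrics.merr) <= 5.0 and sd <= 8.0
    raise ConfigurationError(f"unknown AAMI mode {mode!r}")


def bland_altman(truth, pred) -> tuple[BlandAltmanStats, pd.DataFrame]:
    """Limits-of-agreement statistics plus a plot-ready per-point export
    (x = pair mean, d = estimated − truth)."""
    y, yh = _check_pair(truth, pred, min_n=2)
    d = yh - y
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    stats = BlandAltmanStats(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        lower_loa=mean_diff - 1.96 * sd_diff,
        upper_loa=mean_diff + 1.96 * sd_diff,
    )
    export = pd.DataFrame({"x": (y + yh) / 2.0, "diff": d})
    return stats, export


def variant_bland_altman(truth, pred) -> pd.DataFrame:
    """Per-point export with the ground truth on the x axis; the agreement
    statistics are identical to :func:`bland_altman`."""
    y, yh = _check_pair(truth, pred)
    return pd.DataFrame({"x": y, "diff": yh - y})


@dataclass(frozen=True)
class TaskReport:
    metrics: ErrorMetrics
    cp: CPTable
    bhs: str
    aami_pass: bool
    bland_altman: BlandAltmanStats


@dataclass
class EvalReport:
    """Per-task agreement summary for SBP, DBP and MAP."""

    tasks: dict[str, TaskReport]

    def to_dict(self) -> dict:
        return {name: asdict(rep) for name, rep in self.tasks.items()}

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def evaluate_task(truth, pred, aami_mode: str = "reported") -> TaskReport:
    metrics = error_metrics(truth, pred)
    cp = cumulative_percentages(truth, pred)
    ba, _ = bland_altman(truth, pred)
    return TaskReport(
        metrics=metrics,
        cp=cp,
        bhs=bhs_grade(cp),
        aami_pass=aami_check(metrics, aami_mode, sd=ba.sd_diff),
        bland_altman=ba,
    )


def evaluate_predictions(
    truth: np.ndarray,
    pred: np.ndarray,
    tasks: tuple[str, ...] = ("sbp", "dbp", "map"),
    aami_mode: str = "reported",
) -> EvalReport:
    """Evaluate an (n, n_tasks) prediction matrix against its truth."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape or truth.shape[1] != len(tasks):
        raise ConfigurationError("truth/pred must be (n, n_tasks) and match tasks")
    return EvalReport(
        tasks={
            t: evaluate_task(truth[:, j], pred[:, j], aami_mode)
            for j, t in enumerate(tasks)
        }
    )
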