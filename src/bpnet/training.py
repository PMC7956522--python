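"""Joint training with adaptive validation-trend task weighting.

The three regression losses (SBP, DBP, MAP) are combined as a weighted sum
L_total = Σ_i θ_i · L_i. The weights start uniform at 1/3 and, from the
second epoch on, are re-derived each epoch from validation statistics: for
each task the mean and standard deviation of the per-batch validation MAE
are computed, their relative epoch-over-epoch trends

    T_mean_i = (L_mean_i(k) − L_mean_i(k−1)) / L_mean_i(k)
    T_std_i  = (L_std_i(k) − L_std_i(k−1)) / L_std_i(k)

are formed, and the raw importance r_i = |T_mean_i · T_std_i| · (L_mean_i +
L_std_i) is normalized to θ_i = r_i / Σ r. A task whose validation loss is
still large and still moving therefore keeps attracting gradient; a task
whose loss has flattened cedes its share. If all raw importances vanish the
weights fall back to uniform.

Optimization is plain mini-batch SGD with momentum, an explicit L2 penalty
on all weights and biases, and multiplicative learning-rate decay when the
training loss plateaus. The per-task training loss is the batch RMSE;
validation statistics use the batch MAE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, TrainingDivergedError
from .labels import LabeledDataset
from .model import ModelConfig, backward, forward, init_params

__all__ = [
    "TaskWeights",
    "ValidationLossStats",
    "TrendStats",
    "TrainConfig",
    "TrainResult",
    "joint_loss",
    "validation_stats",
    "compute_trends",
    "update_weights",
    "train",
]

_EPS = 1e-12


@dataclass(frozen=True)
class TaskWeights:
    """Convex task-importance weights (each ≥ 0, summing to 1)."""

    values: tuple[float, ...]

    def __post_init__(self):
        v = np.asarray(self.values)
        if np.any(v < 0) or abs(float(v.sum()) - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")

    @classmethod
    def uniform(cls, n_tasks: int = 3) -> "TaskWeights":
        return cls(values=tuple([1.0 / n_tasks] * n_tasks))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values)


@dataclass(frozen=True)
class ValidationLossStats:
    """Mean/std of per-batch validation MAE at one epoch, per task."""

    epoch: int
    means: tuple[float, ...]
    stds: tuple[float, ...]
    n_batches: int

    def __post_init__(self):
        if self.n_batches < 2:
            raise ConfigurationError(
                "validation statistics need at least 2 batches (std undefined)"
            )
        if any(m < 0 for m in self.means) or any(s < 0 for s in self.stds):
            raise ValueError("loss statistics must be nonnegative")


@dataclass(frozen=True)
class TrendStats:
    """Relative epoch-over-epoch change of the validation statistics."""

    mean_trends: tuple[float, ...]
    std_trends: tuple[float, ...]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer schedule and weighting mode.

    Defaults follow the momentum-SGD recipe the model was designed around:
    learning rate 8e-4, batch 128, momentum 0.9, L2 factor 0.1 on every
    weight and bias, learning rate × 0.9 after 4 epochs without training
    -loss improvement. ``max_epochs`` defaults to a 30-epoch desk run (the
    full-scale schedule is 500).
    """

    learning_rate: float = 8e-4
    batch_size: int = 128
    momentum: float = 0.9
    lr_decay_factor: float = 0.9
    lr_patience: int = 4
    weight_decay: float = 0.1
    max_epochs: int = 30
    seed: int = 0
    loss_kind: str = "rmse"  # per-task training loss: "rmse", "mae" or "mse"
    uniform_weights: bool = False  # ablation: fix every task weight at 1
    val_batch_size: int | None = None  # default: split validation into 4 batches

    def validate(self) -> None:
        if min(self.learning_rate, self.lr_decay_factor) <= 0 or self.batch_size < 1:
            raise ConfigurationError("rates and batch size must be positive")
        if self.lr_patience < 1 or self.max_epochs < 1:
            raise ConfigurationError("patience and max_epochs must be >= 1")
        if self.loss_kind not in ("rmse", "mae", "mse"):
            raise ConfigurationError(f"unknown loss_kind {self.loss_kind!r}")


def _task_loss_and_grad(err: np.ndarray, kind: str):
    """Loss and d(loss)/d(pred) for one task given err = pred − truth."""
    n = len(err)
    if kind == "mse":
        return float(np.mean(err**2)), 2.0 * err / n
    if kind == "mae":
        return float(np.mean(np.abs(err))), np.sign(err) / n
    mse = float(np.mean(err**2))
    rmse = np.sqrt(mse)
    grad = err / (n * rmse) if rmse > _EPS else np.zeros_like(err)
    return rmse, grad


def joint_loss(
    pred_batch: np.ndarray,
    target_batch: np.ndarray,
    weights,
    loss_kind: str = "rmse",
):
    """Weighted multitask loss.

    Returns ``(total, per_task, dpreds)`` where ``per_task`` are the
    unweighted task losses and ``dpreds`` is d(total)/d(pred_batch).
    ``weights`` may be a :class:`TaskWeights` or any array of per-task
    weights (the uniform-weights ablation uses 1.0 per task).
    """
    preds = np.asarray(pred_batch, dtype=float)
    targets = np.asarray(target_batch, dtype=float)
    if preds.shape != targets.shape:
        raise ConfigurationError(f"shape mismatch {preds.shape} vs {targets.shape}")
    if not np.all(np.isfinite(preds)):
        raise TrainingDivergedError("non-finite predictions in joint loss")
    w = weights.as_array() if isinstance(weights, TaskWeights) else np.asarray(weights)
    per_task = np.empty(preds.shape[1])
    dpreds = np.empty_like(preds)
    for j in range(preds.shape[1]):
        loss, grad = _task_loss_and_grad(preds[:, j] - targets[:, j], loss_kind)
        per_task[j] = loss
        dpreds[:, j] = w[j] * grad
    return float(np.dot(w, per_task)), per_task, dpreds


def validation_stats(
    params: dict,
    model_cfg: ModelConfig,
    X_val: np.ndarray,
    y_val: np.ndarray,
    batch_size: int,
    epoch: int,
) -> ValidationLossStats:
    """Per-task mean and population std of batch MAEs on the validation set.

    The model is only read, never updated; batches are taken in a fixed
    order so the statistics are deterministic.
    """
    n = len(X_val)
    n_batches = n // batch_size
    if n_batches < 2:
        raise ConfigurationError(
            f"validation set of {n} segments yields {n_batches} batches of "
            f"{batch_size}; need at least 2"
        )
    maes = np.empty((n_batches, y_val.shape[1]))
    for m in range(n_batches):
        sl = slice(m * batch_size, (m + 1) * batch_size)
        preds, _ = forward(params, X_val[sl], model_cfg)
        maes[m] = np.mean(np.abs(preds - y_val[sl]), axis=0)
    return ValidationLossStats(
        epoch=epoch,
        means=tuple(float(v) for v in maes.mean(axis=0)),
        stds=tuple(float(v) for v in maes.std(axis=0)),  # population convention
        n_batches=n_batches,
    )


def compute_trends(curr: ValidationLossStats, prev: ValidationLossStats) -> TrendStats:
    """Relative change of each statistic, normalized by the current value."""
    if curr.epoch != prev.epoch + 1:
        raise ConfigurationError(
            f"trend needs consecutive epochs, got {prev.epoch} -> {curr.epoch}"
        )
    mean_t = tuple(
        (c - p) / max(c, _EPS) for c, p in zip(curr.means, prev.means)
    )
    std_t = tuple((c - p) / max(c, _EPS) for c, p in zip(curr.stds, prev.stds))
    return TrendStats(mean_trends=mean_t, std_trends=std_t)


def update_weights(trends: TrendStats, stats: ValidationLossStats) -> TaskWeights:
    """Normalize raw importances |T_mean·T_std|·(L_mean + L_std).

    Falls back to uniform weights when every raw importance vanishes (e.g.
    a frozen model whose statistics stop moving).
    """
    raw = np.array(
        [
            abs(tm * ts) * (m + s)
            for tm, ts, m, s in zip(
                trends.mean_trends, trends.std_trends, stats.means, stats.stds
            )
        ]
    )
    total = float(raw.sum())
    if total < _EPS:
        return TaskWeights.uniform(len(raw))
    return TaskWeights(values=tuple(float(r / total) for r in raw))


@dataclass
class TrainResult:
    params: dict
    log: pd.DataFrame
    model_cfg: ModelConfig
    train_cfg: TrainConfig
    history: list = field(default_factory=list)  # ValidationLossStats per epoch


def train(
    train_data: LabeledDataset,
    val_data: LabeledDataset,
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    init: dict | None = None,
) -> TrainResult:
    """Run the joint training loop.

    Per epoch: momentum-SGD updates on shuffled mini-batches with the
    weighted training loss and L2 penalty, then a validation pass producing
    the per-task batch-MAE statistics; from the second epoch on, the task
    weights are re-derived from the statistics' trends. Fully deterministic
    given ``cfg.seed`` and the data.
    """
    cfg.validate()
    model_cfg.validate()
    n_tasks = model_cfg.n_tasks
    if train_data.y.shape[1] != n_tasks or val_data.y.shape[1] != n_tasks:
        raise ConfigurationError(
            f"targets have {train_data.y.shape[1]} columns, model expects {n_tasks}"
        )
    if len(train_data) == 0:
        raise ConfigurationError("empty training set")

    params = {k: v.copy() for k, v in (init or init_params(model_cfg, cfg.seed)).items()}
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    if cfg.uniform_weights:
        weights = np.ones(n_tasks)  # the fixed-weight baseline uses 1 per task
    else:
        weights = TaskWeights.uniform(n_tasks)
    val_bs = cfg.val_batch_size or max(1, len(val_data) // 4)
    lr = cfg.learning_rate
    best_train = np.inf
    bad_epochs = 0
    prev_stats = None
    rows = []
    history = []
    last_good = None

    for epoch in range(cfg.max_epochs):
        order = np.random.default_rng([cfg.seed, 5, epoch]).permutation(len(train_data))
        batch_losses = []
        w_arr = weights.as_array() if isinstance(weights, TaskWeights) else weights
        try:
            for b0 in range(0, len(order) - cfg.batch_size + 1, cfg.batch_size):
                idx = order[b0 : b0 + cfg.batch_size]
                preds, cache = forward(params, train_data.X[idx], model_cfg)
                total, _, dpreds = joint_loss(
                    preds, train_data.y[idx], w_arr, cfg.loss_kind
                )
                grads = backward(dpreds, cache, params, model_cfg)
                penalty = 0.0
                for k in params:
                    penalty += 0.5 * cfg.weight_decay * float(np.sum(params[k] ** 2))
                    g = grads[k] + cfg.weight_decay * params[k]
                    velocity[k] = cfg.momentum * velocity[k] - lr * g
                    params[k] += velocity[k]
                batch_losses.append(total + penalty)
            if len(order) < cfg.batch_size:
                raise ConfigurationError(
                    f"training set of {len(order)} segments smaller than one "
                    f"batch of {cfg.batch_size}"
                )
            if not np.all([np.isfinite(v).all() for v in params.values()]):
                raise TrainingDivergedError(
                    f"non-finite parameters at epoch {epoch}", last_good
                )
        except TrainingDivergedError as e:
            raise TrainingDivergedError(str(e), last_good) from None

        train_loss = float(np.mean(batch_losses))
        # learning-rate plateau schedule on the training loss
        if train_loss < best_train - 1e-10:
            best_train = train_loss
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.lr_patience:
                lr *= cfg.lr_decay_factor
                bad_epochs = 0

        stats = validation_stats(
            params, model_cfg, val_data.X, val_data.y, val_bs, epoch
        )
        history.append(stats)
        if not cfg.uniform_weights and epoch > 0:
            trends = compute_trends(stats, prev_stats)
            weights = update_weights(trends, stats)
        prev_stats = stats

        row = {"epoch": epoch, "lr": lr, "train_loss": train_loss}
        w_arr = weights.as_array() if isinstance(weights, TaskWeights) else weights
        for j, task in enumerate(model_cfg.tasks):
            row[f"theta_{task}"] = float(w_arr[j])
            row[f"val_mean_{task}"] = stats.means[j]
            row[f"val_std_{task}"] = stats.stds[j]
        rows.append(row)
        last_good = {k: v.copy() for k, v in params.items()}

    return TrainResult(
        params=params,
        log=pd.DataFrame(rows),
        model_cfg=model_cfg,
        train_cfg=cfg,
        history=history,
    )
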