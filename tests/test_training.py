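"""Joint loss, validation statistics, trend-based weighting, training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpnet.errors import ConfigurationError, TrainingDivergedError
from bpnet.labels import LabeledDataset
from bpnet.model import ModelConfig, init_params
from bpnet.training import (
    TaskWeights,
    TrainConfig,
    TrendStats,
    ValidationLossStats,
    compute_trends,
    joint_loss,
    train,
    update_weights,
    validation_stats,
)
import pandas as pd


def _tiny_data(n, cfg, y_fn, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, cfg.segment_len))
    y = y_fn(n)
    return LabeledDataset(X=X, y=y, meta=pd.DataFrame(index=range(n)))


class TestJointLoss:
    def test_perfect_predictions_zero_loss(self):
        y = np.array([[120.0, 60.0, 80.0], [110.0, 70.0, 83.3]])
        total, per_task, dpreds = joint_loss(y, y, TaskWeights.uniform())
        assert total == 0.0
        assert np.all(per_task == 0.0) and np.all(dpreds == 0.0)

    def test_weight_masking_isolates_one_task(self):
        truth = np.array([[100.0, 60.0, 70.0], [100.0, 60.0, 70.0]])
        pred = truth + np.array([[3.0, 5.0, 5.0], [4.0, 5.0, 5.0]])
        total, _, _ = joint_loss(pred, truth, np.array([1.0, 0.0, 0.0]))
        assert total == pytest.approx(np.sqrt(12.5))

    def test_hand_computed_rmse_example(self):
        # batch of 2: SBP errors {3, 4}, other tasks perfect, uniform weights
        truth = np.array([[100.0, 60.0, 70.0], [100.0, 60.0, 70.0]])
        pred = truth + np.array([[3.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        total, per_task, _ = joint_loss(pred, truth, TaskWeights.uniform())
        assert per_task[0] == pytest.approx(np.sqrt(12.5))
        assert total == pytest.approx(np.sqrt(12.5) / 3.0)

    @pytest.mark.parametrize(
        "kind,expected", [("rmse", np.sqrt(12.5)), ("mae", 3.5), ("mse", 12.5)]
    )
    def test_loss_kinds(self, kind, expected):
        truth = np.zeros((2, 1))
        pred = np.array([[3.0], [4.0]])
        total, _, _ = joint_loss(pred, truth, np.array([1.0]), kind)
        assert total == pytest.approx(expected)

    def test_nonfinite_predictions_raise_divergence(self):
        y = np.zeros((2, 3))
        bad = np.array([[np.inf, 0, 0], [0, 0, 0]])
        with pytest.raises(TrainingDivergedError):
            joint_loss(bad, y, TaskWeights.uniform())

    def test_gradient_is_weighted(self):
        truth = np.zeros((2, 3))
        pred = np.ones((2, 3))
        _, _, d_uniform = joint_loss(pred, truth, TaskWeights.uniform())
        _, _, d_masked = joint_loss(pred, truth, np.array([1.0, 0.0, 0.0]))
        assert np.all(d_masked[:, 1:] == 0.0)
        assert np.allclose(d_masked[:, 0], 3 * d_uniform[:, 0])


class TestValidationStats:
    def _constant_model(self, value=0.0):
        cfg = ModelConfig(seq_len=2, step_dim=5, hidden_size=2,
                          head_hidden_1=4, head_hidden_2=2)
        params = {k: np.zeros_like(v) for k, v in init_params(cfg, 0).items()}
        for task in cfg.tasks:
            params[f"head_{task}_b3"][:] = value
        return cfg, params

    def test_explicit_batch_maes(self):
        # three batches whose per-batch MAEs are {1, 2, 3} for every task:
        # a zero-predicting model and constant targets 1, 2, 3 per batch
        cfg, params = self._constant_model(0.0)
        X = np.zeros((6, cfg.segment_len))
        y = np.repeat(np.array([[1.0], [2.0], [3.0]]), 2, axis=0) @ np.ones((1, 3))
        stats = validation_stats(params, cfg, X, y, batch_size=2, epoch=0)
        assert stats.n_batches == 3
        assert np.allclose(stats.means, 2.0)
        assert np.allclose(stats.stds, np.sqrt(2.0 / 3.0))  # population std

    def test_perfect_model_all_zero(self):
        cfg, params = self._constant_model(80.0)
        X = np.zeros((4, cfg.segment_len))
        y = np.full((4, 3), 80.0)
        stats = validation_stats(params, cfg, X, y, batch_size=2, epoch=0)
        assert np.all(np.asarray(stats.means) == 0.0)
        assert np.all(np.asarray(stats.stds) == 0.0)

    def test_identical_batches_zero_std(self):
        cfg, params = self._constant_model(0.0)
        X = np.zeros((4, cfg.segment_len))
        y = np.full((4, 3), 5.0)
        stats = validation_stats(params, cfg, X, y, batch_size=2, epoch=0)
        assert np.all(np.asarray(stats.stds) == 0.0)
        assert np.allclose(stats.means, 5.0)

    def test_fewer_than_two_batches_rejected(self):
        cfg, params = self._constant_model(0.0)
        with pytest.raises(ConfigurationError):
            validation_stats(params, cfg, np.zeros((3, cfg.segment_len)),
                             np.zeros((3, 3)), batch_size=2, epoch=0)


class TestTrends:
    def _stats(self, epoch, means, stds=(1.0, 1.0, 1.0)):
        return ValidationLossStats(epoch=epoch, means=means, stds=stds, n_batches=4)

    @pytest.mark.parametrize(
        "curr,prev,expected", [(2.0, 1.0, 0.5), (1.0, 1.0, 0.0), (1.0, 2.0, -1.0)]
    )
    def test_relative_trend_values(self, curr, prev, expected):
        t = compute_trends(
            self._stats(1, (curr, 1.0, 1.0)), self._stats(0, (prev, 1.0, 1.0))
        )
        assert t.mean_trends[0] == pytest.approx(expected)

    def test_non_consecutive_epochs_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_trends(self._stats(3, (1, 1, 1)), self._stats(1, (1, 1, 1)))


class TestUpdateWeights:
    def test_symmetric_tasks_get_uniform_weights(self):
        trends = TrendStats(mean_trends=(0.2, 0.2, 0.2), std_trends=(0.1, 0.1, 0.1))
        stats = ValidationLossStats(0, (5.0, 5.0, 5.0), (1.0, 1.0, 1.0), 4)
        w = update_weights(trends, stats)
        assert np.allclose(w.as_array(), 1 / 3)

    def test_direct_normalization_example(self):
        # raw importances (2, 1, 1) -> weights (0.5, 0.25, 0.25)
        trends = TrendStats(mean_trends=(1.0, 1.0, 1.0), std_trends=(1.0, 1.0, 1.0))
        stats = ValidationLossStats(0, (2.0, 1.0, 1.0), (0.0, 0.0, 0.0), 4)
        w = update_weights(trends, stats)
        assert np.allclose(w.as_array(), [0.5, 0.25, 0.25])

    def test_vanishing_importances_fall_back_to_uniform(self):
        trends = TrendStats(mean_trends=(0.0, 0.0, 0.0), std_trends=(0.0, 0.0, 0.0))
        stats = ValidationLossStats(0, (5.0, 5.0, 5.0), (1.0, 1.0, 1.0), 4)
        assert np.allclose(update_weights(trends, stats).as_array(), 1 / 3)

    def test_mixed_sign_trends_still_normalize(self):
        trends = TrendStats(mean_trends=(-0.5, 0.5, -0.1), std_trends=(0.3, -0.2, 0.4))
        stats = ValidationLossStats(0, (3.0, 2.0, 1.0), (1.0, 0.5, 0.2), 4)
        w = update_weights(trends, stats).as_array()
        assert np.all(w >= 0.0) and np.isclose(w.sum(), 1.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(-2, 2, allow_nan=False), min_size=3, max_size=3),
        st.lists(st.floats(-2, 2, allow_nan=False), min_size=3, max_size=3),
        st.lists(st.floats(0, 50, allow_nan=False), min_size=3, max_size=3),
    )
    def test_always_a_convex_combination(self, tm, ts, means):
        trends = TrendStats(mean_trends=tuple(tm), std_trends=tuple(ts))
        stats = ValidationLossStats(0, tuple(means), (1.0, 1.0, 1.0), 4)
        w = update_weights(trends, stats).as_array()
        assert np.all(w >= 0.0) and np.all(w <= 1.0)
        assert np.isclose(w.sum(), 1.0, atol=1e-9)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            TaskWeights(values=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            TaskWeights(values=(-0.1, 0.6, 0.5))


class TestTrainLoop:
    CFG = ModelConfig(seq_len=2, step_dim=5, hidden_size=4,
                      head_hidden_1=8, head_hidden_2=4)

    def _data(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, self.CFG.segment_len))
        y = np.column_stack(
            [rng.normal(120, 5, n), rng.normal(60, 3, n), rng.normal(80, 4, n)]
        )
        return LabeledDataset(X=X, y=y, meta=pd.DataFrame(index=range(n)))

    def test_epoch_zero_weights_stay_uniform(self):
        res = train(self._data(), self._data(seed=1), self.CFG,
                    TrainConfig(max_epochs=1, batch_size=8, val_batch_size=4))
        row = res.log.iloc[0]
        assert row[["theta_sbp", "theta_dbp", "theta_map"]].tolist() == [1 / 3] * 3

    def test_uniform_ablation_fixes_weights_at_one(self):
        res = train(self._data(), self._data(seed=1), self.CFG,
                    TrainConfig(max_epochs=3, batch_size=8, val_batch_size=4,
                                uniform_weights=True))
        for t in ("sbp", "dbp", "map"):
            assert np.all(res.log[f"theta_{t}"] == 1.0)

    def test_weights_remain_convex_every_epoch(self):
        res = train(self._data(), self._data(seed=1), self.CFG,
                    TrainConfig(max_epochs=5, batch_size=8, val_batch_size=4))
        thetas = res.log[["theta_sbp", "theta_dbp", "theta_map"]].to_numpy()
        assert np.all(thetas >= 0.0)
        assert np.allclose(thetas.sum(axis=1), 1.0, atol=1e-9)

    def test_frozen_model_settles_to_uniform_fallback(self):
        # a vanishing learning rate leaves the model unchanged, so trends are
        # zero from the second epoch on and the fallback applies
        res = train(self._data(), self._data(seed=1), self.CFG,
                    TrainConfig(max_epochs=4, batch_size=8, val_batch_size=4,
                                learning_rate=1e-300))
        thetas = res.log[["theta_sbp", "theta_dbp", "theta_map"]].to_numpy()
        assert np.allclose(thetas[1:], 1 / 3)

    def test_identical_runs_reproduce_theta_trajectory(self):
        kw = dict(max_epochs=4, batch_size=8, val_batch_size=4, seed=3)
        a = train(self._data(), self._data(seed=1), self.CFG, TrainConfig(**kw))
        b = train(self._data(), self._data(seed=1), self.CFG, TrainConfig(**kw))
        assert a.log.equals(b.log)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_single_task_uses_identical_trunk_code(self):
        cfg1 = ModelConfig(seq_len=2, step_dim=5, hidden_size=4,
                           head_hidden_1=8, head_hidden_2=4, tasks=("sbp",))
        data = self._data()
        data1 = LabeledDataset(X=data.X, y=data.y[:, :1], meta=data.meta)
        res = train(data1, data1, cfg1,
                    TrainConfig(max_epochs=2, batch_size=8, val_batch_size=4,
                                uniform_weights=True))
        assert set(res.log.columns) >= {"theta_sbp", "val_mean_sbp"}
        assert "theta_dbp" not in res.log.columns

    def test_train_set_smaller_than_batch_rejected(self):
        with pytest.raises(ConfigurationError):
            train(self._data(n=4), self._data(seed=1), self.CFG,
                  TrainConfig(max_epochs=1, batch_size=8, val_batch_size=4))

    def test_target_column_mismatch_rejected(self):
        data = self._data()
        bad = LabeledDataset(X=data.X, y=data.y[:, :2], meta=data.meta)
        with pytest.raises(ConfigurationError):
            train(bad, bad, self.CFG, TrainConfig(max_epochs=1, batch_size=8))
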