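"""The multitask blood-pressure network.

A 10-s normalized ECG segment (1000 samples at 100 Hz) is folded into a
sequence of 20 steps × 50 samples and passed through a shared 2-layer
bidirectional LSTM trunk. The final hidden state of the forward recurrence
and the final hidden state of the backward recurrence (last layer) are
concatenated into a vector of width 2·hidden, which feeds three identical
but independently parameterized fully connected heads — affine + ReLU,
affine + ReLU, affine → scalar — producing SBP, DBP and MAP estimates in
mmHg. A single-task variant uses the same trunk with one head.

All parameters live in a flat ``dict[str, np.ndarray]``; gradients mirror
that structure, which keeps the momentum-SGD update in the training module
trivial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import linear_backward, linear_forward, lstm_backward, lstm_forward

__all__ = ["ModelConfig", "init_params", "reshape_segment", "forward", "backward",
           "param_count", "predict", "TASKS"]

TASKS = ("sbp", "dbp", "map")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``seq_len`` × ``step_dim`` must equal the segment length; the first head
    width must equal the trunk output width 2·hidden (the concatenated
    bidirectional state).
    """

    seq_len: int = 20
    step_dim: int = 50
    hidden_size: int = 256
    trunk_layers: int = 2
    head_hidden_1: int = 512
    head_hidden_2: int = 256
    tasks: tuple[str, ...] = TASKS

    @property
    def segment_len(self) -> int:
        return self.seq_len * self.step_dim

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    def validate(self) -> None:
        if self.head_hidden_1 != 2 * self.hidden_size:
            raise ValueError(
                "head_hidden_1 must equal the trunk output width 2*hidden_size"
            )
        if self.trunk_layers < 1 or self.n_tasks < 1:
            raise ValueError("need at least one trunk layer and one task")
        if any(t not in TASKS for t in self.tasks):
            raise ValueError(f"tasks must be drawn from {TASKS}")

    @classmethod
    def desk_scale(cls, tasks: tuple[str, ...] = TASKS) -> "ModelConfig":
        """Small configuration for CPU-only runs (hidden 64, heads 128/64)."""
        return cls(hidden_size=64, head_hidden_1=128, head_hidden_2=64, tasks=tasks)


def _lstm_param_shapes(cfg: ModelConfig):
    shapes = {}
    for layer in range(cfg.trunk_layers):
        d_in = cfg.step_dim if layer == 0 else 2 * cfg.hidden_size
        for direction in ("fw", "bw"):
            p = f"trunk{layer}_{direction}"
            shapes[f"{p}_Wx"] = (d_in, 4 * cfg.hidden_size)
            shapes[f"{p}_Wh"] = (cfg.hidden_size, 4 * cfg.hidden_size)
            shapes[f"{p}_b"] = (4 * cfg.hidden_size,)
    return shapes


def _head_param_shapes(cfg: ModelConfig):
    shapes = {}
    d0 = 2 * cfg.hidden_size
    for task in cfg.tasks:
        shapes[f"head_{task}_W1"] = (d0, cfg.head_hidden_1)
        shapes[f"head_{task}_b1"] = (cfg.head_hidden_1,)
        shapes[f"head_{task}_W2"] = (cfg.head_hidden_1, cfg.head_hidden_2)
        shapes[f"head_{task}_b2"] = (cfg.head_hidden_2,)
        shapes[f"head_{task}_W3"] = (cfg.head_hidden_2, 1)
        shapes[f"head_{task}_b3"] = (1,)
    return shapes


def init_params(cfg: ModelConfig, seed: int) -> dict[str, np.ndarray]:
    """Draw every weight and bias from U(−1/√hidden, 1/√hidden), excluding
    exact zeros; deterministic given ``seed``."""
    cfg.validate()
    rng = np.random.default_rng([seed, 4])
    d = 1.0 / np.sqrt(cfg.hidden_size)
    params = {}
    shapes = {**_lstm_param_shapes(cfg), **_head_param_shapes(cfg)}
    for name, shape in shapes.items():
        w = rng.uniform(-d, d, size=shape)
        while np.any(w == 0.0):  # pragma: no cover - probability ~0
            w[w == 0.0] = rng.uniform(-d, d, size=int(np.sum(w == 0.0)))
        params[name] = w
    return params


def param_count(cfg: ModelConfig, trunk_only: bool = False) -> int:
    shapes = _lstm_param_shapes(cfg)
    if not trunk_only:
        shapes = {**shapes, **_head_param_shapes(cfg)}
    return sum(int(np.prod(s)) for s in shapes.values())


def reshape_segment(samples: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """Fold flat segments of length seq_len·step_dim into (…, seq_len,
    step_dim), preserving sample order (step 0 = first step_dim samples)."""
    x = np.asarray(samples, dtype=float)
    if x.shape[-1] != cfg.segment_len:
        raise ValueError(
            f"segment length {x.shape[-1]} != expected "
            f"{cfg.segment_len} (= {cfg.seq_len} steps x {cfg.step_dim})"
        )
    return x.reshape(*x.shape[:-1], cfg.seq_len, cfg.step_dim)


def _trunk_forward(params, x, cfg):
    caches = []
    inp = x
    for layer in range(cfg.trunk_layers):
        p = f"trunk{layer}"
        pf = {k: params[f"{p}_fw_{k}"] for k in ("Wx", "Wh", "b")}
        pb = {k: params[f"{p}_bw_{k}"] for k in ("Wx", "Wh", "b")}
        hf, cf = lstm_forward(inp, pf, reverse=False)
        hb, cb = lstm_forward(inp, pb, reverse=True)
        caches.append((cf, cb))
        inp = np.concatenate([hf, hb], axis=2)
    # final states of the last layer: forward at t=T-1, backward at t=0
    feat = np.concatenate([inp[:, -1, : cfg.hidden_size], inp[:, 0, cfg.hidden_size :]], axis=1)
    return feat, (caches, inp.shape)


def forward(params: dict, X: np.ndarray, cfg: ModelConfig):
    """Batched forward pass.

    ``X`` is (B, segment_len) or already (B, seq_len, step_dim). Returns
    ``(preds, cache)`` with ``preds`` of shape (B, n_tasks), ordered like
    ``cfg.tasks``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == cfg.segment_len:
        X = reshape_segment(X, cfg)
    if X.ndim != 3 or X.shape[1:] != (cfg.seq_len, cfg.step_dim):
        raise ValueError(
            f"expected input of shape (B, {cfg.seq_len}, {cfg.step_dim}) "
            f"or (B, {cfg.segment_len}), got {X.shape}"
        )
    feat, trunk_cache = _trunk_forward(params, X, cfg)
    preds = np.empty((X.shape[0], cfg.n_tasks))
    head_caches = {}
    for j, task in enumerate(cfg.tasks):
        p = f"head_{task}"
        a1, x1 = linear_forward(feat, params[f"{p}_W1"], params[f"{p}_b1"])
        r1 = np.maximum(a1, 0.0)
        a2, x2 = linear_forward(r1, params[f"{p}_W2"], params[f"{p}_b2"])
        r2 = np.maximum(a2, 0.0)
        out, x3 = linear_forward(r2, params[f"{p}_W3"], params[f"{p}_b3"])
        preds[:, j] = out[:, 0]
        head_caches[task] = (x1, a1, x2, a2, x3)
    return preds, {"trunk": trunk_cache, "heads": head_caches, "feat": feat}


def backward(dpreds: np.ndarray, cache: dict, params: dict, cfg: ModelConfig):
    """Gradients of a scalar loss given d(loss)/d(preds)."""
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dfeat = np.zeros_like(cache["feat"])
    for j, task in enumerate(cfg.tasks):
        p = f"head_{task}"
        x1, a1, x2, a2, x3 = cache["heads"][task]
        dout = dpreds[:, j : j + 1]
        dr2, g3 = linear_backward(dout, x3, params[f"{p}_W3"])
        da2 = dr2 * (a2 > 0)
        dr1, g2 = linear_backward(da2, x2, params[f"{p}_W2"])
        da1 = dr1 * (a1 > 0)
        df, g1 = linear_backward(da1, x1, params[f"{p}_W1"])
        dfeat += df
        for i, g in ((1, g1), (2, g2), (3, g3)):
            grads[f"{p}_W{i}"] += g["W"]
            grads[f"{p}_b{i}"] += g["b"]

    caches, out_shape = cache["trunk"]
    B, T, _ = out_shape
    H = cfg.hidden_size
    # route the readout gradient to the two final hidden states
    d_out = np.zeros(out_shape)
    d_out[:, -1, :H] = dfeat[:, :H]
    d_out[:, 0, H:] = dfeat[:, H:]
    for layer in range(cfg.trunk_layers - 1, -1, -1):
        p = f"trunk{layer}"
        cf, cb = caches[layer]
        pf = {k: params[f"{p}_fw_{k}"] for k in ("Wx", "Wh", "b")}
        pb = {k: params[f"{p}_bw_{k}"] for k in ("Wx", "Wh", "b")}
        dxf, gf = lstm_backward(d_out[:, :, :H], cf, pf)
        dxb, gb = lstm_backward(d_out[:, :, H:], cb, pb)
        for k in ("Wx", "Wh", "b"):
            grads[f"{p}_fw_{k}"] += gf[k]
            grads[f"{p}_bw_{k}"] += gb[k]
        d_out = dxf + dxb  # becomes gradient w.r.t. the previous layer's output
    return grads


def predict(params: dict, X: np.ndarray, cfg: ModelConfig, batch_size: int = 256) -> np.ndarray:
    """Forward pass in evaluation mode, batched for memory."""
    X = np.asarray(X, dtype=float)
    outs = []
    for i in range(0, len(X), batch_size):
        preds, _ = forward(params, X[i : i + batch_size], cfg)
        outs.append(preds)
    return np.vstack(outs) if outs else np.empty((0, cfg.n_tasks))
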