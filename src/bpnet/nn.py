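"""Minimal NumPy neural-network primitives with explicit backprop.

Implements exactly what the blood-pressure model needs: a batched LSTM pass
(run forward or reversed in time) and affine layers, each returning the
caches required for analytic gradients. Gate layout in the packed weight
matrices is [input, forget, cell, output], each of width ``hidden``.

Parameters for one LSTM direction are a dict with keys ``Wx`` (in_dim, 4H),
``Wh`` (H, 4H) and ``b`` (4H,). Gradients mirror the parameter structure.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lstm_forward", "lstm_backward", "linear_forward", "linear_backward", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def lstm_forward(x: np.ndarray, params: dict, reverse: bool = False):
    """Run one LSTM direction over a batch.

    Parameters
    ----------
    x : (B, T, D) input sequence in original time order.
    params : dict with ``Wx``, ``Wh``, ``b``.
    reverse : process time steps from last to first (the output array is
        still indexed in original time order, so for a reversed pass the
        direction's final hidden state sits at ``hs[:, 0]``).

    Returns ``(hs, cache)`` with ``hs`` of shape (B, T, H).
    """
    Wx, Wh, b = params["Wx"], params["Wh"], params["b"]
    B, T, _ = x.shape
    H = Wh.shape[0]
    hs = np.zeros((B, T, H))
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    order = range(T - 1, -1, -1) if reverse else range(T)
    steps = []
    for t in order:
        z = x[:, t] @ Wx + h @ Wh + b
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        steps.append((t, h, c, i, f, g, o, tc))
        h, c = h_new, c_new
        hs[:, t] = h
    cache = {"x": x, "steps": steps, "H": H, "reverse": reverse}
    return hs, cache


def lstm_backward(dhs: np.ndarray, cache: dict, params: dict):
    """Backprop through :func:`lstm_forward`.

    ``dhs`` is the gradient w.r.t. the full output array ``hs`` (zeros where
    a time step's output is unused). Returns ``(dx, grads)``.
    """
    Wx, Wh = params["Wx"], params["Wh"]
    x, steps, H = cache["x"], cache["steps"], cache["H"]
    B, T, D = x.shape
    dx = np.zeros_like(x)
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros_like(params["b"])
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t, h_prev, c_prev, i, f, g, o, tc in reversed(steps):
        dh = dhs[:, t] + dh_next
        dc = dc_next + dh * o * (1.0 - tc * tc)
        do = dh * tc
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += x[:, t].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ Wx.T
        dh_next = dz @ Wh.T
        dc_next = dc * f
    return dx, {"Wx": dWx, "Wh": dWh, "b": db}


def linear_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W + b, x


def linear_backward(dy: np.ndarray, x: np.ndarray, W: np.ndarray):
    return dy @ W.T, {"W": x.T @ dy, "b": dy.sum(axis=0)}
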