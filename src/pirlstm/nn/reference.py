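"""Naive, from-the-update-rules LSTM cell written with explicit scalar loops.

This module is a numerical oracle: it evaluates the gate equations

    i_t  = sigmoid(W_i [H_{t-1}, X_t] + B_i)        (input gate)
    Cbar = tanh   (W_c [H_{t-1}, X_t] + B_c)        (candidate)
    f_t  = sigmoid(W_f [H_{t-1}, X_t] + B_f)        (forget gate)
    C_t  = f_t * C_{t-1} + i_t * Cbar               (cell state)
    o_t  = sigmoid(W_o [H_{t-1}, X_t] + B_o)        (output gate)
    H_t  = o_t * tanh(C_t)                          (hidden state)

one scalar at a time, using only the ``math`` module — no array code shared
with the production path — so agreement between the two is meaningful.
It is deliberately slow and used only in tests and self-checks.
"""

from __future__ import annotations

import math
from typing import Sequence

__all__ = ["reference_cell_step", "reference_layer_forward"]


def _sigmoid(v: float) -> float:
    if v >= 0:
        return 1.0 / (1.0 + math.exp(-v))
    e = math.exp(v)
    return e / (1.0 + e)


def _affine(W: Sequence[Sequence[float]], b: Sequence[float],
            h_prev: Sequence[float], x: Sequence[float]) -> list[float]:
    """Row-by-row W.[h_prev, x] + b with explicit loops."""
    concat = list(h_prev) + list(x)
    out = []
    for row, bias in zip(W, b):
        acc = bias
        for w, v in zip(row, concat):
            acc += w * v
        out.append(acc)
    return out


def reference_cell_step(
    W_i, b_i, W_f, b_f, W_o, b_o, W_c, b_c,
    h_prev: Sequence[float], c_prev: Sequence[float], x: Sequence[float],
) -> tuple[list[float], list[float]]:
    """One LSTM step on plain Python lists; returns (h_t, c_t)."""
    i_t = [_sigmoid(v) for v in _affine(W_i, b_i, h_prev, x)]
    f_t = [_sigmoid(v) for v in _affine(W_f, b_f, h_prev, x)]
    o_t = [_sigmoid(v) for v in _affine(W_o, b_o, h_prev, x)]
    cbar = [math.tanh(v) for v in _affine(W_c, b_c, h_prev, x)]
    c_t = [f * c + i * g for f, c, i, g in zip(f_t, c_prev, i_t, cbar)]
    h_t = [o * math.tanh(c) for o, c in zip(o_t, c_t)]
    return h_t, c_t


def reference_layer_forward(
    W_i, b_i, W_f, b_f, W_o, b_o, W_c, b_c,
    inputs: Sequence[Sequence[float]], length: int | None = None,
) -> tuple[list[float], list[float], list[list[float]]]:
    """Chain :func:`reference_cell_step` from zero state over ``length`` steps.

    Returns (h_final, c_final, hidden_trace).
    """
    H = len(b_i)
    h = [0.0] * H
    c = [0.0] * H
    n = len(inputs) if length is None else length
    trace: list[list[float]] = []
    for t in range(n):
        h, c = reference_cell_step(W_i, b_i, W_f, b_f, W_o, b_o, W_c, b_c,
                                   h, c, inputs[t])
        trace.append(list(h))
    return h, c, trace
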