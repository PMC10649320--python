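"""Stacked LSTM classifier network: forward, backward, and checkpointing.

Architecture: a stack of LSTM layers (default 3 layers of 32 hidden units)
reading one-hot base vectors, batch normalization of the top layer's hidden
state at each sequence's true last position, dropout regularization, and a
linear head of size hidden_size x 2 producing piRNA / non-piRNA logits
(index 1 = piRNA).

Everything is plain float64 NumPy.  The backward pass is hand-derived
backpropagation through time; it is validated against finite differences and
the scalar reference cell in the test suite.

Variable lengths are handled by tail padding plus masking: at time steps at
or beyond a sequence's true length the recurrent state is carried through
unchanged, so the state after the last processed step equals the state at
the true last base and padding rows are provably inert.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import dataclass
from typing import Literal

import numpy as np

from ..encoding import EncodedBatch

__all__ = [
    "NetworkConfig",
    "LstmLayerParams",
    "NetworkWeights",
    "init_weights",
    "lstm_cell_step",
    "lstm_layer_forward",
    "network_forward",
    "network_forward_backward",
    "predict_classes",
    "softmax",
    "save_checkpoint",
    "load_checkpoint",
]

BN_EPS = 1e-5
BN_MOMENTUM = 0.1

# gate slice order inside the stacked weight matrix
_I, _F, _O, _G = 0, 1, 2, 3


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters."""

    n_layers: int = 3
    hidden_size: int = 32
    dropout_rate: float = 0.2
    input_size: int = 4
    output_classes: int = 2

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.hidden_size < 1:
            raise ValueError("n_layers and hidden_size must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class LstmLayerParams:
    """Gate parameters of one layer, stacked as W: (4H, H+D), b: (4H,).

    Gate order along the first axis is input, forget, output, candidate.
    The affine input is the concatenation [H_{t-1}, X_t] (hidden first).
    """

    W: np.ndarray
    b: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.b.shape[0] // 4

    def gate(self, which: int) -> tuple[np.ndarray, np.ndarray]:
        H = self.hidden_size
        return self.W[which * H:(which + 1) * H], self.b[which * H:(which + 1) * H]

    # named accessors used by the oracle tests
    @property
    def input_gate(self):    return self.gate(_I)
    @property
    def forget_gate(self):   return self.gate(_F)
    @property
    def output_gate(self):   return self.gate(_O)
    @property
    def candidate(self):     return self.gate(_G)


@dataclass
class NetworkWeights:
    """All trainable arrays plus batch-norm running moments."""

    layers: list[LstmLayerParams]
    bn_gamma: np.ndarray
    bn_beta: np.ndarray
    bn_mean: np.ndarray      # running moments, updated in train mode
    bn_var: np.ndarray
    head_W: np.ndarray       # (2, H)
    head_b: np.ndarray       # (2,)
    bn_batches_seen: int = 0

    def trainable(self) -> list[tuple[str, np.ndarray]]:
        out: list[tuple[str, np.ndarray]] = []
        for k, lay in enumerate(self.layers):
            out.append((f"layer{k}.W", lay.W))
            out.append((f"layer{k}.b", lay.b))
        out += [("bn_gamma", self.bn_gamma), ("bn_beta", self.bn_beta),
                ("head_W", self.head_W), ("head_b", self.head_b)]
        return out


def init_weights(cfg: NetworkConfig, rng: np.random.Generator) -> NetworkWeights:
    """Uniform +-1/sqrt(H) init for all matrices; forget-gate bias offset +1."""
    H = cfg.hidden_size
    k = 1.0 / np.sqrt(H)
    layers = []
    for layer in range(cfg.n_layers):
        D = cfg.input_size if layer == 0 else H
        W = rng.uniform(-k, k, size=(4 * H, H + D))
        b = np.zeros(4 * H)
        b[_F * H:(_F + 1) * H] = 1.0  # forget-gate bias: retain memory early on
        layers.append(LstmLayerParams(W=W, b=b))
    return NetworkWeights(
        layers=layers,
        bn_gamma=np.ones(H), bn_beta=np.zeros(H),
        bn_mean=np.zeros(H), bn_var=np.ones(H),
        head_W=rng.uniform(-k, k, size=(cfg.output_classes, H)),
        head_b=np.zeros(cfg.output_classes),
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def lstm_cell_step(params: LstmLayerParams, prev: tuple[np.ndarray, np.ndarray],
                   x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-vector LSTM update; returns (h_t, c_t)."""
    h_prev, c_prev = prev
    H = params.hidden_size
    z = params.W @ np.concatenate([h_prev, x]) + params.b
    i = _sigmoid(z[_I * H:(_I + 1) * H])
    f = _sigmoid(z[_F * H:(_F + 1) * H])
    o = _sigmoid(z[_O * H:(_O + 1) * H])
    g = np.tanh(z[_G * H:(_G + 1) * H])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c


def _layer_forward(params: LstmLayerParams, X: np.ndarray, lengths: np.ndarray,
                   want_cache: bool):
    """Vectorized masked forward of one layer.

    X: (B, L, D); returns (trace (B, L, H), h_final (B, H), cache).
    At steps t >= lengths[b] the state of item b is carried unchanged, so
    h_final == state at the true last base.
    """
    B, L, D = X.shape
    H = params.hidden_size
    Wh = params.W[:, :H]           # (4H, H)
    Wx = params.W[:, H:]           # (4H, D)
    xz = X.reshape(B * L, D) @ Wx.T
    xz = xz.reshape(B, L, 4 * H) + params.b
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    trace = np.empty((B, L, H))
    cache = [] if want_cache else None
    for t in range(L):
        z = xz[:, t] + h @ Wh.T
        i = _sigmoid(z[:, _I * H:(_I + 1) * H])
        f = _sigmoid(z[:, _F * H:(_F + 1) * H])
        o = _sigmoid(z[:, _O * H:(_O + 1) * H])
        g = np.tanh(z[:, _G * H:(_G + 1) * H])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        m = (t < lengths)[:, None]
        if want_cache:
            cache.append((h, c, i, f, o, g, tc, m))
        c = np.where(m, c_new, c)
        h = np.where(m, h_new, h)
        trace[:, t] = h
    return trace, h, cache


def lstm_layer_forward(params: LstmLayerParams, inputs: np.ndarray,
                       length: int | None = None):
    """Run one layer over a single sequence from zero state.

    inputs: (L, D); only the first ``length`` rows are consumed.
    Returns ((h_final, c_final), hidden_trace of shape (length, H)).
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    L = inputs.shape[0]
    n = L if length is None else length
    if n < 1:
        raise ValueError("length must be >= 1")
    if n > L:
        raise ValueError(f"length {n} exceeds number of input vectors {L}")
    trace, hf, cache = _layer_forward(params, inputs[None, :n], np.array([n]), True)
    h_prev, c_prev, i, f, o, g, tc, m = cache[-1]
    c_final = f * c_prev + i * g
    return (hf[0], c_final[0]), trace[0]


def _dropout_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray | None:
    if rate <= 0.0:
        return None
    return (rng.random(shape) >= rate) / (1.0 - rate)


def _forward(cfg: NetworkConfig, w: NetworkWeights, batch: EncodedBatch,
             mode: Literal["train", "eval"], rng: np.random.Generator | None,
             want_cache: bool):
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    train = mode == "train"
    if train and cfg.dropout_rate > 0 and rng is None:
        raise ValueError("train mode with dropout requires an rng")
    if not train and w.bn_batches_seen == 0:
        raise RuntimeError("eval mode before any training batch: "
                           "batch-norm running moments do not exist yet")
    X = np.asarray(batch.tensor, dtype=np.float64)
    lengths = np.asarray(batch.lengths)
    B = X.shape[0]
    caches = []
    drop_masks = []
    inp = X
    h_final = None
    for k, lay in enumerate(w.layers):
        trace, h_final, cache = _layer_forward(lay, inp, lengths, want_cache)
        caches.append((cache, inp))
        if k < len(w.layers) - 1:
            mask = _dropout_mask(trace.shape, cfg.dropout_rate, rng) if train else None
            drop_masks.append(mask)
            inp = trace * mask if mask is not None else trace
        else:
            inp = trace

    # batch normalization of the final hidden state
    if train:
        mu = h_final.mean(axis=0)
        var = h_final.var(axis=0)
        if B > 1:
            run_var = h_final.var(axis=0, ddof=1)
        else:
            run_var = var
        w.bn_mean = (1 - BN_MOMENTUM) * w.bn_mean + BN_MOMENTUM * mu
        w.bn_var = (1 - BN_MOMENTUM) * w.bn_var + BN_MOMENTUM * run_var
        w.bn_batches_seen += 1
    else:
        mu, var = w.bn_mean, w.bn_var
    inv_std = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (h_final - mu) * inv_std
    embed = w.bn_gamma * xhat + w.bn_beta

    head_mask = _dropout_mask(embed.shape, cfg.dropout_rate, rng) if train else None
    embed_d = embed * head_mask if head_mask is not None else embed
    logits = embed_d @ w.head_W.T + w.head_b
    if not want_cache:
        return logits, None
    return logits, {
        "caches": caches, "drop_masks": drop_masks, "h_final": h_final,
        "xhat": xhat, "inv_std": inv_std, "embed_d": embed_d,
        "head_mask": head_mask, "lengths": lengths,
    }


def network_forward(cfg: NetworkConfig, w: NetworkWeights, batch: EncodedBatch,
                    mode: Literal["train", "eval"] = "eval",
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Forward pass; returns (B, 2) logits."""
    logits, _ = _forward(cfg, w, batch, mode, rng, want_cache=False)
    return logits


def network_forward_backward(cfg: NetworkConfig, w: NetworkWeights,
                             batch: EncodedBatch, labels: np.ndarray,
                             rng: np.random.Generator | None):
    """Train-mode forward plus full backward pass.

    Returns (loss, logits, grads) with grads keyed like
    :meth:`NetworkWeights.trainable`.
    """
    logits, ctx = _forward(cfg, w, batch, "train", rng, want_cache=True)
    B = logits.shape[0]
    p = softmax(logits)
    labels = np.asarray(labels, dtype=np.int64)
    loss = float(-np.mean(np.log(np.maximum(p[np.arange(B), labels], 1e-300))))

    dlogits = p.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= B

    grads: dict[str, np.ndarray] = {}
    grads["head_W"] = dlogits.T @ ctx["embed_d"]
    grads["head_b"] = dlogits.sum(axis=0)
    dembed = dlogits @ w.head_W
    if ctx["head_mask"] is not None:
        dembed = dembed * ctx["head_mask"]
    xhat, inv_std = ctx["xhat"], ctx["inv_std"]
    grads["bn_gamma"] = (dembed * xhat).sum(axis=0)
    grads["bn_beta"] = dembed.sum(axis=0)
    dxhat = dembed * w.bn_gamma
    dh_final = (inv_std / B) * (
        B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
    )

    d_after = None  # gradient w.r.t. the (possibly dropped-out) trace fed upward
    for k in range(len(w.layers) - 1, -1, -1):
        cache, layer_input = ctx["caches"][k]
        L = layer_input.shape[1]
        H = cfg.hidden_size
        if d_after is None:
            d_trace = np.zeros((B, L, H))
            d_extra = dh_final
        else:
            d_trace = d_after
            d_extra = None
        dW, db, dX = _masked_layer_backward(w.layers[k], cache, layer_input,
                                            d_trace, d_extra)
        grads[f"layer{k}.W"] = dW
        grads[f"layer{k}.b"] = db
        if k > 0:
            mask = ctx["drop_masks"][k - 1]
            d_after = dX * mask if mask is not None else dX
    return loss, logits, grads


def _masked_layer_backward(params: LstmLayerParams, cache, X: np.ndarray,
                           d_trace: np.ndarray, d_h_extra: np.ndarray | None):
    """BPTT through one masked layer (inputs X needed for dW)."""
    H = params.hidden_size
    Wh = params.W[:, :H]
    Wx = params.W[:, H:]
    B, L, D = X.shape
    dW = np.zeros_like(params.W)
    db = np.zeros_like(params.b)
    dX = np.empty((B, L, D))
    dh = np.zeros((B, H)) if d_h_extra is None else d_h_extra.copy()
    dc = np.zeros((B, H))
    for t in range(L - 1, -1, -1):
        h_prev, c_prev, i, f, o, g, tc, m = cache[t]
        dh = dh + d_trace[:, t]
        dh_new = np.where(m, dh, 0.0)
        dc_new = np.where(m, dc, 0.0)
        dh_pass = np.where(m, 0.0, dh)
        dc_pass = np.where(m, 0.0, dc)
        do = dh_new * tc
        dct = dc_new + dh_new * o * (1.0 - tc * tc)
        df = dct * c_prev
        di = dct * g
        dg = dct * i
        dc_prev = dct * f
        dz = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            do * o * (1.0 - o),
            dg * (1.0 - g * g),
        ], axis=1)
        dW[:, :H] += dz.T @ h_prev
        dW[:, H:] += dz.T @ X[:, t]
        db += dz.sum(axis=0)
        dX[:, t] = dz @ Wx
        dh = dh_pass + dz @ Wh
        dc = dc_pass + dc_prev
    return dW, db, dX


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_classes(logits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hardened predictions from logits.

    Returns (classes, scores): class 1 = piRNA, 0 = non-piRNA; an exact tie
    goes to non-piRNA; score is the softmax probability of the chosen class.
    """
    logits = np.asarray(logits, dtype=np.float64)
    if logits.ndim != 2 or logits.shape[1] != 2:
        raise ValueError(f"expected (B, 2) logits, got {logits.shape}")
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    p = softmax(logits)
    classes = (logits[:, 1] > logits[:, 0]).astype(np.int64)
    scores = p[np.arange(len(p)), classes]
    return classes, scores


# --- checkpoint archive ------------------------------------------------------

def save_checkpoint(path, cfg: NetworkConfig, w: NetworkWeights,
                    extra: dict | None = None) -> None:
    """Single-archive checkpoint: config JSON + all named arrays (npz)."""
    meta = {
        "config": {"n_layers": cfg.n_layers, "hidden_size": cfg.hidden_size,
                   "dropout_rate": cfg.dropout_rate, "input_size": cfg.input_size,
                   "output_classes": cfg.output_classes},
        "bn_batches_seen": w.bn_batches_seen,
        "extra": extra or {},
    }
    arrays = dict(w.trainable())
    arrays["bn_mean"] = w.bn_mean
    arrays["bn_var"] = w.bn_var
    buf = _io.BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        zf.writestr("arrays.npz", buf.getvalue())


def load_checkpoint(path) -> tuple[NetworkConfig, NetworkWeights, dict]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = np.load(_io.BytesIO(zf.read("arrays.npz")))
        cfg = NetworkConfig(**meta["config"])
        layers = [LstmLayerParams(W=arrays[f"layer{k}.W"], b=arrays[f"layer{k}.b"])
                  for k in range(cfg.n_layers)]
        w = NetworkWeights(
            layers=layers,
            bn_gamma=arrays["bn_gamma"], bn_beta=arrays["bn_beta"],
            bn_mean=arrays["bn_mean"], bn_var=arrays["bn_var"],
            head_W=arrays["head_W"], head_b=arrays["head_b"],
            bn_batches_seen=int(meta["bn_batches_seen"]),
        )
    return cfg, w, meta.get("extra", {})
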