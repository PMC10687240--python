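"""Deterministic multilayer recurrent classifiers in plain numpy.

Implements stacked LSTM / GRU / tanh-RNN layers with a linear read-out on
the final time-step, trained with binary cross-entropy on the sigmoid
output and an Adam optimizer.  Forward and backward passes are written by
hand and validated against finite differences in the test suite; all
randomness flows through explicit generators, so training is bit-for-bit
reproducible for a fixed seed on one platform.

Parameter layout follows the common convention: per layer ``l``,
``Wx_l (D_in, g*H)``, ``Wh_l (H, g*H)``, ``bx_l``, ``bh_l`` with ``g`` =
4 (LSTM: input, forget, cell, output gates), 3 (GRU: reset, update,
candidate) or 1 (RNN); plus a read-out ``Wy (H, 1)``, ``by (1,)``.
"""

from __future__ import annotations

import numpy as np

CELL_GATES = {"lstm": 4, "gru": 3, "rnn": 1}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def init_params(
    input_size: int,
    hidden_size: int,
    n_layers: int,
    cell_kind: str,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Uniform(-k, k) initialization with k = 1/sqrt(hidden_size)."""
    if cell_kind not in CELL_GATES:
        raise ValueError(f"unknown cell kind {cell_kind!r}")
    g = CELL_GATES[cell_kind]
    k = 1.0 / np.sqrt(hidden_size)
    params: dict[str, np.ndarray] = {}
    d_in = input_size
    for layer in range(n_layers):
        params[f"Wx{layer}"] = rng.uniform(-k, k, size=(d_in, g * hidden_size))
        params[f"Wh{layer}"] = rng.uniform(-k, k, size=(hidden_size, g * hidden_size))
        params[f"bx{layer}"] = rng.uniform(-k, k, size=g * hidden_size)
        params[f"bh{layer}"] = rng.uniform(-k, k, size=g * hidden_size)
        d_in = hidden_size
    params["Wy"] = rng.uniform(-k, k, size=(hidden_size, 1))
    params["by"] = rng.uniform(-k, k, size=1)
    return params


# ----- single-layer unrolls ----------------------------------------------


def _layer_forward(kind, X, Wx, Wh, bx, bh):
    """Unroll one recurrent layer over (B, T, D) inputs; cache for backward."""
    B, T, _ = X.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    out = np.empty((B, T, H))
    caches = []
    for t in range(T):
        x = X[:, t, :]
        if kind == "lstm":
            a = x @ Wx + bx + h @ Wh + bh
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            gg = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_new = f * c + i * gg
            h_new = o * np.tanh(c_new)
            caches.append((x, h, c, i, f, gg, o, c_new))
            h, c = h_new, c_new
        elif kind == "gru":
            gi = x @ Wx + bx
            gh = h @ Wh + bh
            r = _sigmoid(gi[:, :H] + gh[:, :H])
            z = _sigmoid(gi[:, H : 2 * H] + gh[:, H : 2 * H])
            n = np.tanh(gi[:, 2 * H :] + r * gh[:, 2 * H :])
            h_new = (1.0 - z) * n + z * h
            caches.append((x, h, r, z, n, gh[:, 2 * H :]))
            h = h_new
        else:  # rnn
            a = x @ Wx + bx + h @ Wh + bh
            h_new = np.tanh(a)
            caches.append((x, h, h_new))
            h = h_new
        out[:, t, :] = h
    return out, caches


def _layer_backward(kind, dout, caches, Wx, Wh):
    """Backprop one layer given d(out) over all time-steps."""
    B, T, H = dout.shape
    D = Wx.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(Wx.shape[1])
    dX = np.empty((B, T, D))
    dh = np.zeros((B, H))
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dh = dh + dout[:, t, :]
        if kind == "lstm":
            x, h_prev, c_prev, i, f, gg, o, c_new = caches[t]
            tc = np.tanh(c_new)
            do = dh * tc
            dc_tot = dc + dh * o * (1.0 - tc * tc)
            di = dc_tot * gg
            df = dc_tot * c_prev
            dg = dc_tot * i
            dc = dc_tot * f
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - gg * gg),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x.T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dX[:, t, :] = da @ Wx.T
            dh = da @ Wh.T
        elif kind == "gru":
            x, h_prev, r, z, n, gh_n = caches[t]
            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z
            dan = dn * (1.0 - n * n)
            dr = dan * gh_n
            dar = dr * r * (1.0 - r)
            daz = dz * z * (1.0 - z)
            dgi = np.concatenate([dar, daz, dan], axis=1)
            dgh = np.concatenate([dar, daz, dan * r], axis=1)
            dWx += x.T @ dgi
            dWh += h_prev.T @ dgh
            db += dgi.sum(axis=0)  # bx; bh gradient tracked separately below
            dX[:, t, :] = dgi @ Wx.T
            dh = dh_prev + dgh @ Wh.T
            caches[t] = caches[t] + (dgh.sum(axis=0),)
        else:
            x, h_prev, h_new = caches[t]
            da = dh * (1.0 - h_new * h_new)
            dWx += x.T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dX[:, t, :] = da @ Wx.T
            dh = da @ Wh.T
    if kind == "gru":
        dbh = np.zeros(Wh.shape[1])
        for t in range(T):
            dbh += caches[t][-1]
        return dWx, dWh, db, dbh, dX
    return dWx, dWh, db, db.copy(), dX


class RecurrentClassifier:
    """Stacked recurrent binary classifier with a final-step linear head.

    Dropout (inverted, sampled per time-step) is applied to the outputs of
    every layer except the top one, and only during training.
    """

    def __init__(
        self,
        input_size: int,
        hidden_size: int,
        n_layers: int,
        cell_kind: str = "lstm",
        dropout: float = 0.0,
        params: dict[str, np.ndarray] | None = None,
        rng: np.random.Generator | None = None,
    ):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if n_layers < 1:
            raise ValueError("need at least one recurrent layer")
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.cell_kind = cell_kind
        self.dropout = dropout
        if params is None:
            rng = rng or np.random.default_rng(0)
            params = init_params(input_size, hidden_size, n_layers, cell_kind, rng)
        self.params = params

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Return final-step logits (B,) and caches for backward."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != self.input_size:
            raise ValueError(
                f"expected input (B, T, {self.input_size}), got {X.shape}"
            )
        p = self.params
        layer_caches = []
        drop_masks = []
        cur = X
        for layer in range(self.n_layers):
            out, caches = _layer_forward(
                self.cell_kind,
                cur,
                p[f"Wx{layer}"],
                p[f"Wh{layer}"],
                p[f"bx{layer}"],
                p[f"bh{layer}"],
            )
            layer_caches.append(caches)
            if training and self.dropout > 0.0 and layer < self.n_layers - 1:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng for dropout")
                m = (rng.uniform(size=out.shape) >= self.dropout) / (
                    1.0 - self.dropout
                )
                drop_masks.append(m)
                cur = out * m
            else:
                drop_masks.append(None)
                cur = out
        h_last = cur[:, -1, :]
        logits = (h_last @ p["Wy"] + p["by"]).ravel()
        cache = (X, layer_caches, drop_masks, cur, h_last)
        return logits, cache

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        X, layer_caches, drop_masks, top_out, h_last = cache
        p = self.params
        grads = {}
        dlog = dlogits.reshape(-1, 1)
        grads["Wy"] = h_last.T @ dlog
        grads["by"] = dlog.sum(axis=0)
        B, T, H = top_out.shape
        dout = np.zeros((B, T, H))
        dout[:, -1, :] = dlog @ p["Wy"].T
        for layer in range(self.n_layers - 1, -1, -1):
            if drop_masks[layer] is not None:
                dout = dout * drop_masks[layer]
            dWx, dWh, dbx, dbh, dX = _layer_backward(
                self.cell_kind,
                dout,
                layer_caches[layer],
                p[f"Wx{layer}"],
                p[f"Wh{layer}"],
            )
            grads[f"Wx{layer}"] = dWx
            grads[f"Wh{layer}"] = dWh
            grads[f"bx{layer}"] = dbx
            grads[f"bh{layer}"] = dbh
            dout = dX
        return grads

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode probabilities in (0, 1)."""
        logits, _ = self.forward(X, training=False)
        return _sigmoid(logits)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on sigmoid(logits); returns (loss, dlogits)."""
    y = np.asarray(y, dtype=float)
    # log(1 + exp(-|z|)) formulation is stable for large |z|
    loss = np.mean(np.maximum(logits, 0.0) - logits * y + np.log1p(np.exp(-np.abs(logits))))
    p = _sigmoid(logits)
    return float(loss), (p - y) / len(y)


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            g = g.reshape(params[k].shape)
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            params[k] -= (
                self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            )


class SGD:
    """Plain SGD, for comparison runs."""

    def __init__(self, params, lr=1e-2):
        self.lr = lr

    def step(self, params, grads) -> None:
        for k, g in grads.items():
            params[k] -= self.lr * g.reshape(params[k].shape)


def make_optimizer(name: str, params, lr: float):
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "sgd":
        return SGD(params, lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")
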