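"""Minimal numpy neural-network engine for the two classifiers.

Contains exactly what the pipeline needs and nothing more: an LSTM sequence
classifier (forward + backpropagation through time), a strided 1-D CNN
(im2col convolutions), inverted dropout, softmax cross-entropy, L2 weight
penalty, global-norm gradient clipping and Adam. Everything is driven by an
explicit ``numpy.random.Generator`` so that training is bit-reproducible
for a given seed.

The L2 penalty is ``beta * mean(w**2)`` summed over weight matrices (biases
excluded); with the published beta values a raw sum of squares would dwarf
the cross-entropy at these parameter counts.
"""
from __future__ import annotations

import numpy as np


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def one_hot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((y.size, k))
    out[np.arange(y.size), y] = 1.0
    return out


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


class Adam:
    """Adam optimiser over a named parameter dict (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            self.params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def clip_grads(grads: dict[str, np.ndarray], max_norm: float | None) -> None:
    if not max_norm:
        return
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale


def l2_penalty(params: dict[str, np.ndarray], beta: float,
               grads: dict[str, np.ndarray] | None = None) -> float:
    """beta * mean(w^2) summed over weight matrices; adds d/dw in place."""
    loss = 0.0
    for k, w in params.items():
        if k.startswith("b"):
            continue
        loss += beta * float(np.mean(w * w))
        if grads is not None:
            grads[k] += beta * 2.0 * w / w.size
    return loss


# ---------------------------------------------------------------------------
# LSTM sequence classifier


class LstmClassifier:
    """Single-layer LSTM over (B, T, n_in) sequences; the last hidden state
    feeds a dense softmax over ``n_out`` classes."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int,
                 rng: np.random.Generator):
        H = n_hidden
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, n_out
        self.params = {
            "Wx": _glorot(rng, n_in, 4 * H),
            "Wh": _glorot(rng, H, 4 * H),
            "bg": np.zeros(4 * H),
            "Wo": _glorot(rng, H, n_out),
            "bo": np.zeros(n_out),
        }
        self.params["bg"][H:2 * H] = 1.0      # forget-gate bias

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def forward(self, X: np.ndarray, want_cache: bool = False):
        p = self.params
        B, T, _ = X.shape
        H = self.n_hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            z = X[:, t] @ p["Wx"] + h @ p["Wh"] + p["bg"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if want_cache:
                cache.append((X[:, t], h, c, i, f, g, o, tc))
            h, c = h_new, c_new
        logits = h @ p["Wo"] + p["bo"]
        probs = softmax(logits)
        return (probs, h, cache) if want_cache else probs

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, beta: float):
        p = self.params
        B, T, _ = X.shape
        H = self.n_hidden
        probs, hT, cache = self.forward(X, want_cache=True)
        Y = one_hot(y, self.n_out)
        ce = -float(np.mean(np.sum(Y * np.log(probs + 1e-12), axis=1)))

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = (probs - Y) / B
        grads["Wo"] = hT.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wo"].T
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g * g),
                do * o * (1 - o),
            ], axis=1)
            grads["Wx"] += x_t.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["bg"] += dz.sum(axis=0)
            dh = dz @ p["Wh"].T
            dc = dc * f
        loss = ce + l2_penalty(p, beta, grads)
        return loss, grads

    def predict_proba(self, X: np.ndarray, batch: int = 512) -> np.ndarray:
        out = np.empty((X.shape[0], self.n_out))
        for i in range(0, X.shape[0], batch):
            out[i:i + batch] = self.forward(X[i:i + batch])
        return out


# ---------------------------------------------------------------------------
# 1-D CNN (conv blocks that halve their input length, then dense layers)


def _same_pad(L: int, k: int, s: int) -> tuple[int, int, int]:
    L_out = -(-L // s)
    total = max((L_out - 1) * s + k - L, 0)
    return L_out, total // 2, total - total // 2


def conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int):
    """x: (B, C, L); W: (C*k, F); returns (y (B, F, L_out), cache)."""
    B, C, L = x.shape
    k = W.shape[0] // C
    L_out, pl, pr = _same_pad(L, k, stride)
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B,C,Lp-k+1,k)
    pos = np.arange(L_out) * stride
    col = win[:, :, pos].transpose(0, 2, 1, 3).reshape(B, L_out, C * k)
    y = col @ W + b
    return y.transpose(0, 2, 1), (col, xp.shape, pos, k, C, stride, pl, L)


def conv1d_backward(dy: np.ndarray, W: np.ndarray, cache):
    col, xp_shape, pos, k, C, stride, pl, L = cache
    B, F, L_out = dy.shape
    dyf = dy.transpose(0, 2, 1)                       # (B, L_out, F)
    dW = col.reshape(-1, C * k).T @ dyf.reshape(-1, F)
    db = dyf.sum(axis=(0, 1))
    dcol = (dyf @ W.T).reshape(B, L_out, C, k).transpose(0, 2, 1, 3)
    dxp = np.zeros(xp_shape)
    for o in range(k):
        dxp[:, :, pos + o] += dcol[:, :, :, o]
    dx = dxp[:, :, pl:pl + L]
    return dx, dW, db


class SleepWakeNet:
    """Five conv blocks (each halves its input length) + two dense layers.

    Input: (B, 2, 300) -- 5 min of 1-Hz IHR and delayed SpO2, each channel
    median-subtracted per window. Output: softmax over (sleep, wake).
    """

    def __init__(self, n_channels: int, input_len: int, n_blocks: int,
                 filters: int, kernel: int, strides: tuple[int, int],
                 fc_nodes: tuple[int, int], n_out: int, dropout_p: float,
                 rng: np.random.Generator):
        self.cfgt = (n_channels, input_len, n_blocks, filters, kernel,
                     strides, fc_nodes, n_out)
        self.dropout_p = dropout_p
        self.params: dict[str, np.ndarray] = {}
        C = n_channels
        L = input_len
        for bidx in range(n_blocks):
            for j, s in enumerate(strides):
                cin = C if (bidx, j) == (0, 0) else filters
                self.params[f"Wc{bidx}{j}"] = _glorot(rng, cin * kernel, filters)
                self.params[f"bc{bidx}{j}"] = np.zeros(filters)
                L = -(-L // s)
        self.flat_len = filters * L
        dims = (self.flat_len, *fc_nodes, n_out)
        for i in range(3):
            self.params[f"Wf{i}"] = _glorot(rng, dims[i], dims[i + 1])
            self.params[f"bf{i}"] = np.zeros(dims[i + 1])

    @property
    def block_output_len(self) -> int:
        return self.flat_len // self.cfgt[3]

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        (_, _, n_blocks, filters, kernel, strides, _, _) = self.cfgt
        p = self.params

        def dropout(a: np.ndarray):
            if train and self.dropout_p > 0:
                m = (rng.random(a.shape) >= self.dropout_p) / (1 - self.dropout_p)
                return a * m, m
            return a, None

        conv_caches = []                  # (key, conv_cache, relu_mask)
        a = X
        for bidx in range(n_blocks):
            for j, s in enumerate(strides):
                key = f"c{bidx}{j}"
                y, cv = conv1d_forward(a, p[f"W{key}"], p[f"b{key}"], s)
                mask = y > 0
                a = y * mask
                conv_caches.append((key, cv, mask))
        a, conv_drop = dropout(a)
        conv_shape = a.shape
        h = a.reshape(a.shape[0], -1)

        fc_caches = []                    # (h_in, relu_mask, drop_mask)
        for i in range(3):
            z = h @ p[f"Wf{i}"] + p[f"bf{i}"]
            if i < 2:
                mask = z > 0
                a2, dmask = dropout(z * mask)
                fc_caches.append((h, mask, dmask))
                h = a2
            else:
                fc_caches.append((h, None, None))
                h = z
        probs = softmax(h)
        return probs, (conv_caches, conv_drop, conv_shape, fc_caches)

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, beta: float,
                       rng: np.random.Generator):
        p = self.params
        probs, (conv_caches, conv_drop, conv_shape, fc_caches) = self.forward(
            X, train=True, rng=rng)
        Y = one_hot(y, probs.shape[1])
        ce = -float(np.mean(np.sum(Y * np.log(probs + 1e-12), axis=1)))
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        d = (probs - Y) / X.shape[0]      # d(loss)/d(logits)
        for i in range(2, -1, -1):
            h_in, mask, dmask = fc_caches[i]
            if mask is not None:          # gradient arrives post-dropout/relu
                if dmask is not None:
                    d = d * dmask
                d = d * mask
            grads[f"Wf{i}"] += h_in.T @ d
            grads[f"bf{i}"] += d.sum(axis=0)
            d = d @ p[f"Wf{i}"].T
        d = d.reshape(conv_shape)
        if conv_drop is not None:
            d = d * conv_drop
        for key, cv, mask in reversed(conv_caches):
            d = d * mask
            d, dW, db = conv1d_backward(d, p[f"W{key}"], cv)
            grads[f"W{key}"] += dW
            grads[f"b{key}"] += db
        loss = ce + l2_penalty(p, beta, grads)
        return loss, grads

    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for i in range(0, X.shape[0], batch):
            probs, _ = self.forward(X[i:i + batch])
            out.append(probs)
        return np.concatenate(out, axis=0)
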