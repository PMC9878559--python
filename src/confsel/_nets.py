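"""Compact NumPy neural networks: MLP (GAN parts), 1-D CNN, stacked LSTM.

Everything here is plain float32 NumPy with hand-written backprop and Adam.
Networks are tiny (tens of units, ~50-long inputs), so single-threaded NumPy
is fast enough and, with seeded ``numpy.random.Generator`` state for init,
shuffling and dropout, training is bit-reproducible.

Losses are binary cross-entropy on logits; gradients use the stable
``sigmoid(logit) - target`` form throughout.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def relu(z):
    return np.maximum(z, 0.0)


def leaky_relu(z, alpha=0.2):
    return np.where(z >= 0, z, alpha * z)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def clip_grads(grads, max_norm):
    total = np.sqrt(sum(float((g * g).sum()) for g in grads))
    if total > max_norm:
        scale = F32(max_norm / (total + 1e-12))
        grads = [g * scale for g in grads]
    return grads


def _he(rng, fan_in, shape):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


# -- fully connected ---------------------------------------------------------


class MLP:
    """Dense stack with a fixed hidden activation and linear (logit) output."""

    def __init__(self, sizes, rng, hidden="relu"):
        self.hidden = hidden
        self.W = [_he(rng, sizes[i], (sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1], dtype=F32) for i in range(len(sizes) - 1)]

    @property
    def params(self):
        return [*self.W, *self.b]

    def _act(self, z):
        return relu(z) if self.hidden == "relu" else leaky_relu(z)

    def _dact(self, z):
        if self.hidden == "relu":
            return (z > 0).astype(F32)
        return np.where(z >= 0, F32(1.0), F32(0.2))

    def forward(self, x):
        zs, hs = [], [x]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = hs[-1] @ W + b
            zs.append(z)
            hs.append(self._act(z) if i < len(self.W) - 1 else z)
        return hs[-1], (zs, hs)

    def backward(self, cache, dout):
        zs, hs = cache
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dout
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = hs[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * self._dact(zs[i - 1])
            else:
                delta = delta @ self.W[i].T
        return [*gW, *gb], delta


# -- 1-D CNN -----------------------------------------------------------------


class Conv1DNet:
    """conv(ReLU) -> dropout -> maxpool -> dense(ReLU) -> logit.

    Input is the ordered descriptor vector treated as a length-d signal with
    one channel.
    """

    def __init__(self, d, rng, filters=32, kernel=3, pool=2, dense=64,
                 dropout=0.2):
        if d < kernel:
            raise ValueError(f"input length {d} shorter than kernel {kernel}")
        self.d, self.k, self.F, self.pool = d, kernel, filters, pool
        self.dropout = dropout
        conv_len = d - kernel + 1
        pooled = conv_len // pool
        flat = pooled * filters
        self.Wc = _he(rng, kernel, (kernel, filters))
        self.bc = np.zeros(filters, dtype=F32)
        self.W1 = _he(rng, flat, (flat, dense))
        self.b1 = np.zeros(dense, dtype=F32)
        self.W2 = _he(rng, dense, (dense, 1))
        self.b2 = np.zeros(1, dtype=F32)

    @property
    def params(self):
        return [self.Wc, self.bc, self.W1, self.b1, self.W2, self.b2]

    def _patches(self, x):
        # (B, conv_len, k) sliding windows
        idx = np.arange(self.d - self.k + 1)[:, None] + np.arange(self.k)[None, :]
        return x[:, idx]

    def forward(self, x, rng=None):
        train = rng is not None
        P = self._patches(x)                       # (B, L, k)
        zc = P @ self.Wc + self.bc                 # (B, L, F)
        a = relu(zc)
        if train and self.dropout > 0:
            mask = (rng.random(a.shape) >= self.dropout).astype(F32)
            a = a * mask / F32(1 - self.dropout)
        else:
            mask = None
        L = a.shape[1] - a.shape[1] % self.pool
        blocks = a[:, :L].reshape(a.shape[0], L // self.pool, self.pool, self.F)
        pooled = blocks.max(axis=2)                # (B, L/p, F)
        arg = blocks.argmax(axis=2)
        flat = pooled.reshape(x.shape[0], -1)
        z1 = flat @ self.W1 + self.b1
        h1 = relu(z1)
        logit = h1 @ self.W2 + self.b2
        cache = (x, P, zc, mask, arg, blocks.shape, flat, z1, h1)
        return logit[:, 0], cache

    def backward(self, cache, dlogit):
        x, P, zc, mask, arg, bshape, flat, z1, h1 = cache
        d2 = dlogit[:, None]
        gW2 = h1.T @ d2
        gb2 = d2.sum(axis=0)
        dh1 = (d2 @ self.W2.T) * (z1 > 0)
        gW1 = flat.T @ dh1
        gb1 = dh1.sum(axis=0)
        dflat = dh1 @ self.W1.T
        B, nblocks, pool, F = bshape
        dpool = dflat.reshape(B, nblocks, F)
        dblocks = np.zeros(bshape, dtype=F32)
        bi, ni, fi = np.ogrid[:B, :nblocks, :F]
        dblocks[bi, ni, arg, fi] = dpool
        da = np.zeros_like(zc)
        da[:, : nblocks * pool] = dblocks.reshape(B, nblocks * pool, F)
        if mask is not None:
            da = da * mask / F32(1 - self.dropout)
        dzc = da * (zc > 0)
        gWc = np.einsum("blk,blf->kf", P, dzc)
        gbc = dzc.sum(axis=(0, 1))
        return [gWc, gbc, gW1, gb1, gW2, gb2]


# -- LSTM --------------------------------------------------------------------


class LSTMLayer:
    """Single LSTM layer; gates sigmoid, cell/output activation ReLU.

    ReLU (rather than tanh) in the cell update mirrors the architecture this
    package targets; stability at these small scales is maintained by global
    gradient-norm clipping in the trainer.
    """

    def __init__(self, d_in, units, rng):
        scale = np.sqrt(1.0 / (d_in + units))
        self.W = (rng.standard_normal((d_in + units, 4 * units)) * scale).astype(F32)
        self.b = np.zeros(4 * units, dtype=F32)
        self.b[units: 2 * units] = 1.0  # forget-gate bias
        self.units = units

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        B, T, _ = x.shape
        H = self.units
        h = np.zeros((B, H), dtype=F32)
        c = np.zeros((B, H), dtype=F32)
        hs = np.empty((B, T, H), dtype=F32)
        caches = []
        for t in range(T):
            xt = np.concatenate([x[:, t], h], axis=1)
            z = xt @ self.W + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H: 2 * H])
            o = sigmoid(z[:, 2 * H: 3 * H])
            g = relu(z[:, 3 * H:])
            c_new = f * c + i * g
            ac = relu(c_new)
            h = o * ac
            hs[:, t] = h
            caches.append((xt, i, f, o, g, c, c_new, ac))
            c = c_new
        return hs, caches

    def backward(self, caches, dhs):
        B, T, H = dhs.shape
        gW = np.zeros_like(self.W)
        gb = np.zeros_like(self.b)
        dh_next = np.zeros((B, H), dtype=F32)
        dc_next = np.zeros((B, H), dtype=F32)
        d_in = self.W.shape[0] - H
        dx = np.empty((B, T, d_in), dtype=F32)
        for t in range(T - 1, -1, -1):
            xt, i, f, o, g, c_prev, c_new, ac = caches[t]
            dh = dhs[:, t] + dh_next
            do = dh * ac
            dc = dh * o * (c_new > 0) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o),
                 dg * (g > 0)], axis=1)
            gW += xt.T @ dz
            gb += dz.sum(axis=0)
            dxt = dz @ self.W.T
            dx[:, t] = dxt[:, :d_in]
            dh_next = dxt[:, d_in:]
            dc_next = dc * f
        return [gW, gb], dx


class LSTMNet:
    """Two stacked LSTM layers -> dropout -> dense(ReLU) -> dropout -> logit."""

    def __init__(self, rng, units=(64, 64), dense=32, dropout=0.2, d_in=1):
        self.l1 = LSTMLayer(d_in, units[0], rng)
        self.l2 = LSTMLayer(units[0], units[1], rng)
        self.W1 = _he(rng, units[1], (units[1], dense))
        self.b1 = np.zeros(dense, dtype=F32)
        self.W2 = _he(rng, dense, (dense, 1))
        self.b2 = np.zeros(1, dtype=F32)
        self.dropout = dropout

    @property
    def params(self):
        return [*self.l1.params, *self.l2.params,
                self.W1, self.b1, self.W2, self.b2]

    def _drop(self, a, rng):
        if rng is None or self.dropout == 0:
            return a, None
        mask = (rng.random(a.shape) >= self.dropout).astype(F32)
        return a * mask / F32(1 - self.dropout), mask

    def forward(self, x, rng=None):
        # x: (B, T) descriptor sequence, one channel per step
        x3 = x[:, :, None].astype(F32)
        h1, c1 = self.l1.forward(x3)
        h1d, m1 = self._drop(h1, rng)
        h2, c2 = self.l2.forward(h1d)
        last = h2[:, -1]
        lastd, m2 = self._drop(last, rng)
        z1 = lastd @ self.W1 + self.b1
        a1 = relu(z1)
        a1d, m3 = self._drop(a1, rng)
        logit = a1d @ self.W2 + self.b2
        cache = (c1, c2, m1, m2, m3, lastd, z1, a1d, h2.shape)
        return logit[:, 0], cache

    def backward(self, cache, dlogit):
        c1, c2, m1, m2, m3, lastd, z1, a1d, h2shape = cache
        keep = F32(1 - self.dropout)
        d2 = dlogit[:, None]
        gW2 = a1d.T @ d2
        gb2 = d2.sum(axis=0)
        da1 = d2 @ self.W2.T
        if m3 is not None:
            da1 = da1 * m3 / keep
        dz1 = da1 * (z1 > 0)
        gW1 = lastd.T @ dz1
        gb1 = dz1.sum(axis=0)
        dlast = dz1 @ self.W1.T
        if m2 is not None:
            dlast = dlast * m2 / keep
        dh2 = np.zeros(h2shape, dtype=F32)
        dh2[:, -1] = dlast
        g2, dh1 = self.l2.backward(c2, dh2)
        if m1 is not None:
            dh1 = dh1 * m1 / keep
        g1, _ = self.l1.backward(c1, dh1)
        return [*g1, *g2, gW1, gb1, gW2, gb2]


# -- training loop -----------------------------------------------------------


def bce_from_logits(logits: np.ndarray, targets: np.ndarray) -> float:
    z, y = logits, targets
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


def train_binary(model, X, y, *, epochs, batch_size, lr, seed, clip=5.0):
    """SGD/Adam loop for a model exposing forward/backward/params on logits."""
    rng = np.random.default_rng(seed)
    X = X.astype(F32)
    y = y.astype(F32)
    opt = Adam(model.params, lr=lr)
    n = len(X)
    for _ in range(epochs):
        order = rng.permutation(n)
        for s in range(0, n, batch_size):
            idx = order[s: s + batch_size]
            logits, cache = model.forward(X[idx], rng=rng)
            dlogit = (sigmoid(logits) - y[idx]) / F32(len(idx))
            grads = model.backward(cache, dlogit)
            opt.step(clip_grads(grads, clip))
    return model


def predict_proba(model, X, batch_size=512):
    out = []
    X = X.astype(F32)
    for s in range(0, len(X), batch_size):
        logits, _ = model.forward(X[s: s + batch_size])
        out.append(sigmoid(logits))
    return np.concatenate(out).astype(float)
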