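"""Minimal NumPy neural-network core: MLP and stacked-LSTM regressors.

Implements exactly what the nociception models need — dense/LSTM forward
passes, manual backpropagation (BPTT for the LSTM), MSE loss, Adam, and
global-norm gradient clipping — with deterministic seeded initialization
and shuffling, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in place)."""

    def __init__(self, params: list, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def clip_global_norm(grads: list, max_norm: float) -> list:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if total > max_norm and total > 0:
        scale = max_norm / total
        return [g * scale for g in grads]
    return grads


class MLPNet:
    """Fully connected regressor: ReLU hidden layers, ReLU output, MSE."""

    def __init__(self, n_in: int, hidden: tuple = (50, 30),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        sizes = [n_in, *hidden, 1]
        self.W = [rng.normal(0, np.sqrt(2.0 / sizes[i]),
                             (sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        # positive output bias keeps the output ReLU initially live
        self.b[-1][:] = 0.5

    @property
    def params(self) -> list:
        return [*self.W, *self.b]

    def forward(self, X: np.ndarray):
        acts = [X]
        pre = []
        h = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            pre.append(z)
            h = np.maximum(z, 0.0)  # ReLU on hidden layers and output
            acts.append(h)
        return h[:, 0], (acts, pre)

    def backward(self, dy: np.ndarray, cache) -> list:
        acts, pre = cache
        delta = dy[:, None] * (pre[-1] > 0)
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            dW[i] = acts[i].T @ delta
            db[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (pre[i - 1] > 0)
        return [*dW, *db]

    def predict(self, X: np.ndarray) -> np.ndarray:
        y, _ = self.forward(X)
        return y


class _LSTMLayer:
    """Single LSTM layer; gate order i, f, g, o; sigmoid/tanh activations."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(n_hidden)
        self.Wx = rng.uniform(-s, s, (n_in, 4 * n_hidden))
        self.Wh = rng.uniform(-s, s, (n_hidden, 4 * n_hidden))
        self.b = np.zeros(4 * n_hidden)
        self.b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias
        self.nh = n_hidden

    @property
    def params(self) -> list:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray):
        """X: (B, T, n_in) -> H: (B, T, nh) with per-step caches."""
        B, T, _ = X.shape
        nh = self.nh
        h = np.zeros((B, nh))
        c = np.zeros((B, nh))
        H = np.empty((B, T, nh))
        caches = []
        for t in range(T):
            a = X[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(a[:, :nh])
            f = _sigmoid(a[:, nh:2 * nh])
            g = np.tanh(a[:, 2 * nh:3 * nh])
            o = _sigmoid(a[:, 3 * nh:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            caches.append((X[:, t, :], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            H[:, t, :] = h
        return H, caches

    def backward(self, dH: np.ndarray, caches) -> tuple:
        """dH: (B, T, nh) gradients w.r.t. each output h_t.

        Returns ``(dX, [dWx, dWh, db])``.
        """
        B, T, nh = dH.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.empty((B, T, self.Wx.shape[0]))
        dh_next = np.zeros((B, nh))
        dc_next = np.zeros((B, nh))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = caches[t]
            dh = dH[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            dWx += x_t.T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dX[:, t, :] = da @ self.Wx.T
            dh_next = da @ self.Wh.T
        return dX, [dWx, dWh, db]


class LSTMNet:
    """Stacked LSTM regressor with a ReLU dense head on the last step."""

    def __init__(self, n_in: int, hidden: tuple = (100, 200),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.layers = []
        prev = n_in
        for nh in hidden:
            self.layers.append(_LSTMLayer(prev, nh, rng))
            prev = nh
        s = 1.0 / np.sqrt(prev)
        self.Wd = rng.uniform(-s, s, (prev, 1))
        self.bd = np.full(1, 0.5)

    @property
    def params(self) -> list:
        out = []
        for lay in self.layers:
            out.extend(lay.params)
        out.extend([self.Wd, self.bd])
        return out

    def forward(self, X: np.ndarray):
        """X: (B, T, n_in) -> predictions (B,)."""
        caches = []
        H = X
        for lay in self.layers:
            H, c = lay.forward(H)
            caches.append(c)
        z = H[:, -1, :] @ self.Wd + self.bd
        y = np.maximum(z, 0.0)
        return y[:, 0], (caches, H, z)

    def backward(self, dy: np.ndarray, cache) -> list:
        caches, H, z = cache
        delta = dy[:, None] * (z > 0)
        dWd = H[:, -1, :].T @ delta
        dbd = delta.sum(axis=0)
        B, T, _ = H.shape
        dH = np.zeros_like(H)
        dH[:, -1, :] = delta @ self.Wd.T
        layer_grads = []
        for lay, c in zip(reversed(self.layers), reversed(caches)):
            dH, grads = lay.backward(dH, c)
            layer_grads.append(grads)
        out = []
        for grads in reversed(layer_grads):
            out.extend(grads)
        out.extend([dWd, dbd])
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        y, _ = self.forward(X)
        return y


def train_regressor(net, X: np.ndarray, y: np.ndarray,
                    X_val: np.ndarray | None = None,
                    y_val: np.ndarray | None = None,
                    epochs: int = 50, batch_size: int = 125,
                    lr: float = 1e-3, grad_clip: float | None = None,
                    rng: np.random.Generator | None = None
                    ) -> tuple[list, list]:
    """Mini-batch Adam/MSE training loop.

    Returns per-epoch ``(train_losses, val_losses)``; raises on NaN loss.
    """
    rng = rng or np.random.default_rng()
    opt = Adam(net.params, lr=lr)
    n = X.shape[0]
    train_losses, val_losses = [], []
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = X[idx], y[idx]
            pred, cache = net.forward(xb)
            err = pred - yb
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/Inf loss at epoch {epoch}, batch start {start}")
            epoch_loss += loss * idx.size
            grads = net.backward(2.0 * err / idx.size, cache)
            if grad_clip is not None:
                grads = clip_global_norm(grads, grad_clip)
            opt.step(grads)
        train_losses.append(epoch_loss / n)
        if X_val is not None and X_val.shape[0] > 0:
            val_pred = net.predict(X_val)
            val_losses.append(float(np.mean((val_pred - y_val) ** 2)))
    return train_losses, val_losses
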