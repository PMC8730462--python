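"""Minimal numpy implementation of the recurrent forecasting network.

The stack is: batch-normalization on the scalar input feature -> one or
more LSTM layers, each followed by (inverted) dropout -> a single linear
output unit, trained with mean-squared-error loss and Adam. Layer
conventions follow Keras so the architecture matches its common
description: LSTM gate order i/f/g/o with unit forget-gate bias, Glorot
uniform kernels and orthogonal recurrent kernels, batch-norm eps 1e-3 and
momentum 0.99, Adam eps 1e-7.

Sequences here are short (the lag count, typically 2-5), so full
backpropagation through time is cheap. All gradients are exact and are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = ["SequenceRegressor", "Adam", "fit_model", "count_parameters"]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot_uniform(rng, shape):
    fan_in, fan_out = shape[0], shape[1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng, n):
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class _BatchNorm:
    """Batch normalization over the scalar input feature (batch x time)."""

    def __init__(self, eps: float = 1e-3, momentum: float = 0.99):
        self.eps = eps
        self.momentum = momentum
        self.params = {"gamma": np.ones(1), "beta": np.zeros(1)}
        self.grads = {"gamma": np.zeros(1), "beta": np.zeros(1)}
        self.running_mean = np.zeros(1)
        self.running_var = np.ones(1)
        self._cache = None

    def forward(self, x, training):
        if training:
            mu = x.mean()
            var = x.var()
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean[0], self.running_var[0]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std)
        return self.params["gamma"][0] * xhat + self.params["beta"][0]

    def backward(self, dout):
        xhat, inv_std = self._cache
        n = xhat.size
        self.grads["gamma"][0] = np.sum(dout * xhat)
        self.grads["beta"][0] = np.sum(dout)
        dxhat = dout * self.params["gamma"][0]
        # batch statistics were part of the forward pass, so they carry gradient
        dx = (inv_std / n) * (
            n * dxhat - np.sum(dxhat) - xhat * np.sum(dxhat * xhat)
        )
        return dx


class _LSTM:
    """One LSTM layer unrolled over the (short) lag dimension."""

    def __init__(self, input_dim, units, return_sequences, rng):
        self.units = units
        self.return_sequences = return_sequences
        kernel = _glorot_uniform(rng, (input_dim, 4 * units))
        recurrent = np.hstack([_orthogonal(rng, units) for _ in range(4)])
        bias = np.zeros(4 * units)
        bias[units : 2 * units] = 1.0  # forget-gate bias starts open
        self.params = {"W": kernel, "U": recurrent, "b": bias}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x, training):
        n, T, _ = x.shape
        H = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        steps = []
        hs = np.empty((n, T, H))
        for t in range(T):
            z = x[:, t, :] @ W + h @ U + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            steps.append((x[:, t, :], h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._cache = (steps, x.shape)
        return hs if self.return_sequences else h

    def backward(self, dout):
        steps, x_shape = self._cache
        n, T, d = x_shape
        H = self.units
        W, U = self.params["W"], self.params["U"]
        for k in self.grads:
            self.grads[k].fill(0.0)
        if self.return_sequences:
            dh_seq = dout
        else:
            dh_seq = np.zeros((n, T, H))
            dh_seq[:, -1, :] = dout
        dx = np.empty((n, T, d))
        dh_next = np.zeros((n, H))
        dc_next = np.zeros((n, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = steps[t]
            dh = dh_seq[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.hstack(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ]
            )
            self.grads["W"] += x_t.T @ dz
            self.grads["U"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, t, :] = dz @ W.T
            dh_next = dz @ U.T
            dc_next = dc * f
        return dx


class _Dropout:
    """Inverted dropout; identity at inference or when rate is 0."""

    def __init__(self, rate):
        self.rate = rate
        self._mask = None

    def forward(self, x, training, rng):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class _Dense:
    """Single linear output unit."""

    def __init__(self, input_dim, rng):
        self.params = {"W": _glorot_uniform(rng, (input_dim, 1)), "b": np.zeros(1)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x):
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        x = self._cache
        self.grads["W"] = x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class SequenceRegressor:
    """Batch-norm -> LSTM stack (dropout after each) -> dense-1 network."""

    def __init__(self, lags, widths, dropout=0.1, seed=0):
        rng = np.random.default_rng(seed)
        self.lags = lags
        self.widths = list(widths)
        self.dropout_rate = dropout
        self.bn = _BatchNorm()
        self.lstms = []
        self.dropouts = []
        d = 1
        for k, w in enumerate(self.widths):
            last = k == len(self.widths) - 1
            self.lstms.append(_LSTM(d, w, return_sequences=not last, rng=rng))
            self.dropouts.append(_Dropout(dropout))
            d = w
        self.dense = _Dense(d, rng)

    # -- forward / backward ------------------------------------------------
    def forward(self, X, training=False, rng=None):
        x = np.asarray(X, dtype=float).reshape(-1, self.lags, 1)
        h = self.bn.forward(x, training)
        for lstm, drop in zip(self.lstms, self.dropouts):
            h = lstm.forward(h, training)
            h = drop.forward(h, training, rng)
        return self.dense.forward(h).ravel()

    def predict(self, X):
        return self.forward(X, training=False)

    def loss_and_grads(self, X, y, rng):
        """MSE loss on one batch plus exact gradients in each layer."""
        pred = self.forward(X, training=True, rng=rng)
        err = pred - np.asarray(y, dtype=float).ravel()
        loss = float(np.mean(err * err))
        if not np.isfinite(loss):
            raise RuntimeError(
                "non-finite training loss; reduce the learning rate"
            )
        dout = (2.0 / err.size) * err.reshape(-1, 1)
        dh = self.dense.backward(dout)
        for lstm, drop in zip(reversed(self.lstms), reversed(self.dropouts)):
            dh = lstm.backward(drop.backward(dh))
        self.bn.backward(dh)
        return loss

    # -- parameter plumbing ------------------------------------------------
    def _layers(self):
        return [self.bn, *self.lstms, self.dense]

    def parameters(self):
        """(layer, name) handles for every trainable array."""
        return [(layer, name) for layer in self._layers() for name in layer.params]

    def get_state(self):
        """Deep copy of all weights and batch-norm running statistics."""
        return copy.deepcopy(
            {
                "params": [
                    {k: v.copy() for k, v in layer.params.items()}
                    for layer in self._layers()
                ],
                "running_mean": self.bn.running_mean.copy(),
                "running_var": self.bn.running_var.copy(),
            }
        )

    def set_state(self, state):
        for layer, saved in zip(self._layers(), state["params"]):
            for k in layer.params:
                layer.params[k] = saved[k].copy()
        self.bn.running_mean = state["running_mean"].copy()
        self.bn.running_var = state["running_var"].copy()


def count_parameters(lags, widths):
    """Closed-form trainable + non-trainable parameter count of the stack."""
    total = 4  # batch-norm gamma/beta + running mean/var
    d = 1
    for w in widths:
        total += 4 * w * (d + w + 1)
        d = w
    total += d + 1
    return total


class Adam:
    """Adaptive-moment gradient descent (Keras defaults)."""

    def __init__(self, learning_rate=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = {}
        self._v = {}

    def step(self, handles):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        scale = self.lr * np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for idx, (layer, name) in enumerate(handles):
            g = layer.grads[name]
            m = self._m.setdefault(idx, np.zeros_like(g))
            v = self._v.setdefault(idx, np.zeros_like(g))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            layer.params[name] -= scale * m / (np.sqrt(v) + self.eps)


def fit_model(
    model: SequenceRegressor,
    X,
    y,
    epochs=100,
    batch_size=256,
    validation_fraction=0.1,
    learning_rate=0.001,
    seed=0,
    resplit_validation=True,
):
    """Train with per-epoch random validation holdout and best-epoch restore.

    Each epoch holds out a seeded random ``validation_fraction`` of rows
    (re-drawn every epoch by default, or fixed once with
    ``resplit_validation=False``), minimizes batch MSE with Adam on the
    rest, and records train/validation loss. After the last epoch the
    weights from the epoch with the lowest validation loss are restored.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n == 0:
        raise ValueError("empty training set")
    n_val = max(1, int(round(validation_fraction * n)))
    if n_val >= n:
        raise ValueError("validation split leaves no training rows")
    rng = np.random.default_rng(seed)
    opt = Adam(learning_rate)
    handles = model.parameters()
    history = {"loss": [], "val_loss": []}
    best_loss, best_state, best_epoch = np.inf, None, -1
    fixed_perm = rng.permutation(n)
    for epoch in range(epochs):
        perm = rng.permutation(n) if resplit_validation else fixed_perm
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        order = tr_idx[rng.permutation(tr_idx.size)]
        losses, weights = [], []
        for start in range(0, order.size, batch_size):
            batch = order[start : start + batch_size]
            loss = model.loss_and_grads(X[batch], y[batch], rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate"
                )
            opt.step(handles)
            losses.append(loss)
            weights.append(batch.size)
        history["loss"].append(float(np.average(losses, weights=weights)))
        val_pred = model.predict(X[val_idx])
        val_loss = float(np.mean((val_pred - y[val_idx]) ** 2))
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history["val_loss"].append(val_loss)
        if val_loss < best_loss:
            best_loss, best_state, best_epoch = val_loss, model.get_state(), epoch
    model.set_state(best_state)
    return history, best_epoch
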