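"""Minimal NumPy sequential-network engine.

Implements exactly the ingredients the classifier comparison needs: dense,
1-D convolutional (filters slide along time over the six signal channels),
average-pooling and LSTM layers, Glorot-uniform initialisation, the Adam
optimiser, binary cross-entropy on logits, mini-batch training with an
early validation stop that restores the best-validation-loss weights.
Everything is deterministic given the seed.  Gradients of every layer are
verified against numerical differentiation in the test suite.

Networks output a single logit; ``Sequential.predict_proba`` applies the
sigmoid.  Computing the loss from logits (softplus form) keeps training
numerically stable in float32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_from_logits(z: np.ndarray, y: np.ndarray) -> float:
    """mean(softplus(z) - y*z), the stable form of binary cross-entropy."""
    z = np.asarray(z, float)
    y = np.asarray(y, float)
    return float(np.mean(np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))))


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _rebind(self) -> None:
        """Refresh named attribute aliases after params were re-viewed."""


class Dense(Layer):
    """Fully connected layer, optional ReLU."""

    def __init__(self, n_in: int, n_out: int, activation: str | None = "relu",
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out, dtype)
        self.b = np.zeros(n_out, dtype)
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _rebind(self):
        self.W, self.b = self.params

    def forward(self, x):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * self._mask
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Conv1D(Layer):
    """1-D convolution along time, valid padding, stride 1, ReLU."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 activation: str | None = "relu",
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.k, self.c, self.f = kernel_size, in_channels, filters
        fan_in = kernel_size * in_channels
        self.W = _glorot(rng, (fan_in, filters), fan_in, filters, dtype)
        self.b = np.zeros(filters, dtype)
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _rebind(self):
        self.W, self.b = self.params

    def forward(self, x):
        # x: (B, T, C) -> (B, L, F) with L = T - k + 1
        b, t, c = x.shape
        L = t - self.k + 1
        win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)
        self._cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(b * L, self.k * c)
        z = (self._cols @ self.W).reshape(b, L, self.f) + self.b
        self._shape = (b, t, c, L)
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        return z

    def backward(self, grad):
        b, t, c, L = self._shape
        if self.activation == "relu":
            grad = grad * self._mask
        g = grad.reshape(b * L, self.f)
        self.grads[0][...] = self._cols.T @ g
        self.grads[1][...] = g.sum(axis=0)
        dx = np.zeros((b, t, c), dtype=grad.dtype)
        Wk = self.W.reshape(self.k, c, self.f)
        for kk in range(self.k):
            dx[:, kk:kk + L, :] += grad @ Wk[kk].T
        return dx


class AvgPool1D(Layer):
    """Non-overlapping temporal average pooling; remainder steps dropped."""

    def __init__(self, pool: int):
        self.pool = pool
        self.params, self.grads = [], []

    def forward(self, x):
        b, t, f = x.shape
        L = t // self.pool
        self._shape = (b, t, f, L)
        return x[:, :L * self.pool].reshape(b, L, self.pool, f).mean(axis=2)

    def backward(self, grad):
        b, t, f, L = self._shape
        dx = np.zeros((b, t, f), dtype=grad.dtype)
        dx[:, :L * self.pool] = np.repeat(grad / self.pool, self.pool, axis=1)
        return dx


class Flatten(Layer):
    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class LSTM(Layer):
    """LSTM layer returning the last hidden state or the full sequence.

    Gate order i, f, g, o; forget-gate bias initialised to 1.
    """

    def __init__(self, in_channels: int, units: int,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 return_sequences: bool = False):
        rng = rng or np.random.default_rng()
        self.u = units
        self.return_sequences = return_sequences
        self.W = _glorot(rng, (in_channels, 4 * units), in_channels, units, dtype)
        self.U = _glorot(rng, (units, 4 * units), units, units, dtype)
        self.b = np.zeros(4 * units, dtype)
        self.b[units:2 * units] = 1.0
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _rebind(self):
        self.W, self.U, self.b = self.params

    def forward(self, x):
        b, t, _ = x.shape
        u = self.u
        h = np.zeros((b, u), dtype=x.dtype)
        cst = np.zeros((b, u), dtype=x.dtype)
        self._x = x
        self._cache = []
        hs = []
        xw = x @ self.W  # (B, T, 4U), precomputed once
        for step in range(t):
            z = xw[:, step] + h @ self.U + self.b
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = sigmoid(z[:, 3 * u:])
            c_prev = cst
            cst = f * c_prev + i * g
            tc = np.tanh(cst)
            self._cache.append((h, c_prev, i, f, g, o, tc))
            h = o * tc
            if self.return_sequences:
                hs.append(h)
        if self.return_sequences:
            return np.stack(hs, axis=1)
        return h

    def backward(self, grad):
        b, t, cin = self._x.shape
        u = self.u
        dW = self.grads[0]; dU = self.grads[1]; db = self.grads[2]
        dW[...] = 0; dU[...] = 0; db[...] = 0
        dx = np.zeros_like(self._x)
        if self.return_sequences:
            dh = grad[:, t - 1]
        else:
            dh = grad
        dc = np.zeros((b, u), dtype=dh.dtype)
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[step]
            do = dh * tc
            dc = dc + dh * o * (1 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            dW += self._x[:, step].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step] = dz @ self.W.T
            dh = dz @ self.U.T
            if self.return_sequences and step > 0:
                dh = dh + grad[:, step - 1]
            dc = dc * f
        return dx


class Sequential:
    """A stack of layers ending in a single-logit head.

    All parameters and gradients live in two flat contiguous buffers (the
    layers hold reshaped views into them), so the optimiser update and
    weight snapshots are single vectorised operations.
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        params = [p for layer in layers for p in layer.params]
        if params:
            self.flat_params = np.concatenate([p.ravel() for p in params])
            self.flat_grads = np.zeros_like(self.flat_params)
        else:  # pragma: no cover - a model with no weights is degenerate
            self.flat_params = np.zeros(0)
            self.flat_grads = np.zeros(0)
        offset = 0
        for layer in layers:
            for k, p in enumerate(layer.params):
                layer.params[k] = self.flat_params[offset:offset + p.size].reshape(p.shape)
                layer.grads[k] = self.flat_grads[offset:offset + p.size].reshape(p.shape)
                offset += p.size
            layer._rebind()

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0]

    def backward(self, grad_logit: np.ndarray) -> None:
        grad = grad_logit[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [sigmoid(self.forward(x[s:s + batch_size]))
               for s in range(0, len(x), batch_size)]
        return np.concatenate(out)

    def parameters(self):
        return [(p, g) for layer in self.layers for p, g in zip(layer.params, layer.grads)]

    def count_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def get_weights(self) -> np.ndarray:
        return self.flat_params.copy()

    def set_weights(self, weights: np.ndarray) -> None:
        self.flat_params[...] = weights


class Adam:
    """Adam with the standard bias-corrected first/second moments."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_val_loss: float = np.inf
    best_epoch: int = -1
    stopped_epoch: int = -1


def fit(model: Sequential, x_train: np.ndarray, y_train: np.ndarray,
        x_val: np.ndarray, y_val: np.ndarray, *,
        batch_size: int = 4, lr: float = 0.001, beta1: float = 0.9,
        beta2: float = 0.999, eps: float = 1e-7, patience: int = 10,
        min_delta: float = 1e-4, max_epochs: int = 500, seed: int = 0) -> History:
    """Train with Adam/BCE and a validation stop.

    Stops once the validation loss has not improved by at least
    ``min_delta`` for ``patience`` consecutive epochs (or at
    ``max_epochs``) and restores the weights of the best-validation-loss
    epoch.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    opt = Adam([(model.flat_params, model.flat_grads)],
               lr=lr, beta1=beta1, beta2=beta2, eps=eps)
    hist = History()
    best_weights = model.get_weights()
    stop_ref = np.inf
    wait = 0
    n = len(x_train)
    y_train = np.asarray(y_train, x_train.dtype)
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, batch_size):
            idx = order[s:s + batch_size]
            xb, yb = x_train[idx], y_train[idx]
            z = model.forward(xb)
            losses.append(bce_from_logits(z, yb))
            grad = (sigmoid(z) - yb) / len(idx)
            model.backward(grad.astype(xb.dtype))
            opt.step()
        hist.train_loss.append(float(np.mean(losses)))
        z_val = np.concatenate([model.forward(x_val[s:s + 256])
                                for s in range(0, len(x_val), 256)])
        vloss = bce_from_logits(z_val, y_val)
        hist.val_loss.append(vloss)
        if vloss < hist.best_val_loss:
            # restore target: the genuinely best state seen
            hist.best_val_loss = vloss
            hist.best_epoch = epoch
            best_weights = model.get_weights()
        if vloss < stop_ref - min_delta:
            # patience only resets on improvements that matter
            stop_ref = vloss
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
    hist.stopped_epoch = epoch
    model.set_weights(best_weights)
    return hist
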