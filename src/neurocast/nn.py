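"""Minimal dense/recurrent network kit used by the forecaster and diagnoser.

Implements exactly the two architectures this package needs — a two-layer
LSTM sequence-to-one regressor and a four-hidden-layer perceptron with a
sigmoid output — trained with mini-batch Adam on a mean-squared-error loss.
All arithmetic is plain float64 numpy, fully deterministic given a seed.

Conventions
-----------
* Every model exposes ``forward(X)``, ``backward(dY)``, ``parameters()``
  and ``gradients()``; :func:`fit` drives the training loop.
* Rectified-linear activations throughout the hidden stack; the LSTM uses
  relu for the candidate/cell activations with conventional sigmoid gates.
* The loss is ``mean((pred - target)**2)`` over the mini-batch.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _drelu(activated: np.ndarray) -> np.ndarray:
    # derivative expressed through the activated value (0 at the kink)
    return (activated > 0.0).astype(activated.dtype)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Dense:
    """Fully connected layer ``y = act(x W + b)``."""

    def __init__(self, in_dim, out_dim, rng, activation="linear", bias_init=0.0):
        self.W = _glorot(rng, in_dim, out_dim)
        self.b = np.full(out_dim, float(bias_init))
        self.activation = activation
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None
        self._y = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            y = relu(z)
        elif self.activation == "sigmoid":
            y = expit(z)
        else:
            y = z
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dz = dy * _drelu(self._y)
        elif self.activation == "sigmoid":
            dz = dy * self._y * (1.0 - self._y)
        else:
            dz = dy
        self.gW = self._x.T @ dz
        self.gb = dz.sum(axis=0)
        return dz @ self.W.T

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.gW, self.gb]


class LSTM:
    """Single LSTM layer, batch-major input of shape (B, T, in_dim).

    Gate order in the packed weight matrices is (input, forget, candidate,
    output); the forget-gate bias starts at 1 so early training does not
    wash out the cell state.
    """

    def __init__(self, in_dim, units, rng, return_sequences=False):
        self.units = units
        self.return_sequences = return_sequences
        self.W = _glorot(rng, in_dim, 4 * units)
        self.U = _glorot(rng, units, 4 * units)
        self.b = np.zeros(4 * units)
        self.b[units : 2 * units] = 1.0
        self.gW = np.zeros_like(self.W)
        self.gU = np.zeros_like(self.U)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        u = self.units
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        steps = []
        hs = np.empty((B, T, u))
        for t in range(T):
            xt = x[:, t, :]
            z = xt @ self.W + h @ self.U + self.b
            i = expit(z[:, :u])
            f = expit(z[:, u : 2 * u])
            g = relu(z[:, 2 * u : 3 * u])
            o = expit(z[:, 3 * u :])
            c_new = f * c + i * g
            hc = relu(c_new)
            h_new = o * hc
            steps.append((xt, h, c, i, f, g, o, c_new, hc))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._cache = (x.shape, steps)
        return hs if self.return_sequences else h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (B, T, in_dim), steps = self._cache
        u = self.units
        self.gW.fill(0.0)
        self.gU.fill(0.0)
        self.gb.fill(0.0)
        dx = np.zeros((B, T, in_dim))
        dh_next = np.zeros((B, u))
        dc_next = np.zeros((B, u))
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, c_new, hc = steps[t]
            if self.return_sequences:
                dh = dh_next + dy[:, t, :]
            else:
                dh = dh_next + (dy if t == T - 1 else 0.0)
            do = dh * hc
            dc = dc_next + dh * o * _drelu(hc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * _drelu(g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.gW += xt.T @ dz
            self.gU += h_prev.T @ dz
            self.gb += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return dx

    def parameters(self):
        return [self.W, self.U, self.b]

    def gradients(self):
        return [self.gW, self.gU, self.gb]


class SequenceRegressor:
    """Two stacked LSTM layers + dense scalar head (relu throughout).

    The dense bias starts at 0.5 so the relu output unit begins live in the
    middle of the normalised score range.
    """

    def __init__(self, units=(32, 16), seed=0):
        rng = np.random.default_rng(seed)
        u1, u2 = units
        self.lstm1 = LSTM(1, u1, rng, return_sequences=True)
        self.lstm2 = LSTM(u1, u2, rng, return_sequences=False)
        self.head = Dense(u2, 1, rng, activation="relu", bias_init=0.5)
        self.units = tuple(units)
        self.seed = seed

    def forward(self, X: np.ndarray) -> np.ndarray:
        # X: (B, T) normalised scores -> (B,) predictions
        h = self.lstm1.forward(X[:, :, None])
        h = self.lstm2.forward(h)
        return self.head.forward(h)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        dh = self.head.backward(dy[:, None])
        dh = self.lstm2.backward(dh)
        self.lstm1.backward(dh)

    def _layers(self):
        return (self.lstm1, self.lstm2, self.head)

    def parameters(self):
        return [p for layer in self._layers() for p in layer.parameters()]

    def gradients(self):
        return [g for layer in self._layers() for g in layer.gradients()]


class MLP:
    """Perceptron with relu hidden layers and a scalar sigmoid output."""

    def __init__(self, in_dim=5, hidden=(32, 16, 8, 4), seed=0):
        rng = np.random.default_rng(seed)
        self.layers = []
        dims = [in_dim, *hidden]
        for a, b in zip(dims[:-1], dims[1:]):
            self.layers.append(Dense(a, b, rng, activation="relu"))
        self.layers.append(Dense(dims[-1], 1, rng, activation="sigmoid"))
        self.hidden = tuple(hidden)
        self.seed = seed

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = X
        for layer in self.layers:
            h = layer.forward(h)
        return h[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        d = dy[:, None]
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self):
        return [g for layer in self.layers for g in layer.gradients()]


class Adam:
    """Adaptive-moment estimation over a fixed parameter list (in place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            mhat = m / (1.0 - b1**self.t)
            vhat = v / (1.0 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def fit(
    model,
    X: np.ndarray,
    y: np.ndarray,
    *,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    epochs: int = 200,
    batch_size: int = 16,
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> dict[str, list[float]]:
    """Mini-batch Adam/MSE training loop; returns per-epoch loss history."""
    if len(X) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    n = len(X)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            pred = model.forward(X[idx])
            dy = 2.0 * (pred - y[idx]) / len(idx)
            model.backward(dy)
            opt.step(model.gradients())
        train_loss = mse(model.forward(X), y)
        if not np.isfinite(train_loss):
            raise TrainingDivergenceError("training loss became non-finite")
        history["train_loss"].append(train_loss)
        if X_val is not None and len(X_val):
            history["val_loss"].append(mse(model.forward(X_val), y_val))
    return history


def weights_to_lists(model) -> list[list]:
    return [p.tolist() for p in model.parameters()]


def weights_from_lists(model, data: list[list]) -> None:
    params = model.parameters()
    if len(params) != len(data):
        raise ValueError("weight list does not match model structure")
    for p, d in zip(params, data):
        arr = np.asarray(d, dtype=float)
        if arr.shape != p.shape:
            raise ValueError(f"weight shape mismatch: {arr.shape} vs {p.shape}")
        p[...] = arr
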