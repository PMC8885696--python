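"""Minimal numpy sequence classifiers for frequency-ordered spectra.

A spectrum is treated as a sequence over frequency, one step per grid point
with features (eps', eps'').  Four architectures are provided:

* ``recurrent_sequence`` -- three stacked LSTM layers with dropout and batch
  normalisation between them, mean-pooled over frequency into a softmax head;
* ``bidirectional_recurrent`` -- the same stack with direction-symmetric
  bidirectional LSTM layers (one weight-tied cell run over the sequence in
  both directions, outputs summed), which makes predictions exactly
  invariant to reversing the frequency order;
* ``residual_bidirectional_recurrent`` -- the bidirectional stack with
  identity skip connections on the upper layers (gradient highways for
  deeper training);
* ``conv1d`` -- two 1-D convolutions with ReLU, global max pooling and a
  softmax head.

Everything is implemented directly on numpy arrays with analytic
backpropagation (gradient-checked in the test suite) and trained with Adam
on a softmax cross-entropy loss plus ridge (L2) weight regularisation.  All
randomness (initialisation, dropout, minibatch order) derives from a single
seed, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SequenceClassifier", "TrainingDiverged", "FAMILIES"]

FAMILIES = (
    "recurrent_sequence",
    "bidirectional_recurrent",
    "residual_bidirectional_recurrent",
    "conv1d",
)


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# layers


class _Layer:
    """Parameterised layer; params/grads are dicts of arrays."""

    regularized: tuple[str, ...] = ()

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, X, train):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(_Layer):
    regularized = ("W",)

    def __init__(self, d_in, d_out, rng):
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.params = {
            "W": rng.normal(0, scale, (d_in, d_out)),
            "b": np.zeros(d_out),
        }

    def forward(self, X, train):
        self._X = X
        return X @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._X.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class LSTM(_Layer):
    """Single unidirectional LSTM layer mapping (B,T,D) -> (B,T,H)."""

    regularized = ("W", "U")

    def __init__(self, d_in, units, rng):
        super().__init__()
        self.units = units
        sw = np.sqrt(1.0 / d_in)
        su = np.sqrt(1.0 / units)
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0  # forget-gate bias
        self.params = {
            "W": rng.normal(0, sw, (d_in, 4 * units)),
            "U": rng.normal(0, su, (units, 4 * units)),
            "b": b,
        }

    def _run(self, X):
        B, T, _ = X.shape
        H = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        out = np.empty((B, T, H))
        for t in range(T):
            a = X[:, t] @ W + h @ U + b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_new = f * c + i * g
            hc = np.tanh(c_new)
            h_new = o * hc
            cache.append((X[:, t], h, c, i, f, g, o, c_new, hc))
            h, c = h_new, c_new
            out[:, t] = h
        return out, cache

    def _run_backward(self, dout, cache):
        B, T, H = dout.shape
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dX = np.empty((B, T, W.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_new, hc = cache[t]
            dh = dout[:, t] + dh_next
            do = dh * hc
            dc = dh * o * (1 - hc * hc) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            da = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dW += x_t.T @ da
            dU += h_prev.T @ da
            db += da.sum(axis=0)
            dX[:, t] = da @ W.T
            dh_next = da @ U.T
            dc_next = dc * f
        return dX, {"W": dW, "U": dU, "b": db}

    def forward(self, X, train):
        out, self._cache = self._run(X)
        return out

    def backward(self, dout):
        dX, self.grads = self._run_backward(dout, self._cache)
        return dX


class BiLSTM(LSTM):
    """Direction-symmetric bidirectional LSTM: one weight-tied cell run
    forward and backward over the sequence, outputs summed.

    Because the two directions share weights and outputs are summed,
    reversing the input sequence exactly reverses the output sequence
    (equivariance); with a pooled head, predictions are reversal-invariant.
    """

    def forward(self, X, train):
        out_f, self._cache_f = self._run(X)
        out_b, self._cache_b = self._run(X[:, ::-1])
        return out_f + out_b[:, ::-1]

    def backward(self, dout):
        dX_f, g_f = self._run_backward(dout, self._cache_f)
        dX_b, g_b = self._run_backward(dout[:, ::-1], self._cache_b)
        self.grads = {k: g_f[k] + g_b[k] for k in g_f}
        return dX_f + dX_b[:, ::-1]


class Residual(_Layer):
    """Identity skip around an inner layer (matching dimensions)."""

    def __init__(self, inner: _Layer):
        super().__init__()
        self.inner = inner

    @property
    def regularized(self):
        return self.inner.regularized

    @property
    def params(self):
        return self.inner.params

    @params.setter
    def params(self, v):
        if v:
            self.inner.params = v

    @property
    def grads(self):
        return self.inner.grads

    @grads.setter
    def grads(self, v):
        if v:
            self.inner.grads = v

    def forward(self, X, train):
        return self.inner.forward(X, train) + X

    def backward(self, dout):
        return self.inner.backward(dout) + dout


class BatchNorm(_Layer):
    """Per-feature batch normalisation over the batch (and time) axes."""

    def __init__(self, d, momentum=0.9, eps=1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(d), "beta": np.zeros(d)}
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)

    def forward(self, X, train):
        axes = tuple(range(X.ndim - 1))
        if train:
            mu = X.mean(axis=axes)
            var = X.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (X - mu) * inv
        if train:
            self._cache = (xhat, inv, axes, X.size // X.shape[-1])
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv, axes, N = self._cache
        gamma = self.params["gamma"]
        self.grads = {
            "gamma": (dout * xhat).sum(axis=axes),
            "beta": dout.sum(axis=axes),
        }
        dxhat = dout * gamma
        return (
            inv
            / N
            * (
                N * dxhat
                - dxhat.sum(axis=axes)
                - xhat * (dxhat * xhat).sum(axis=axes)
            )
        )


class Dropout(_Layer):
    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, X, train):
        if not train or self.rate == 0:
            self._mask = None
            return X
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(X.shape) < keep) / keep
        return X * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Conv1D(_Layer):
    """Same-padded 1-D convolution over the time axis, (B,T,D) -> (B,T,C)."""

    regularized = ("W",)

    def __init__(self, d_in, channels, kernel, rng):
        super().__init__()
        self.kernel = kernel
        scale = np.sqrt(2.0 / (d_in * kernel))
        self.params = {
            "W": rng.normal(0, scale, (kernel, d_in, channels)),
            "b": np.zeros(channels),
        }

    def forward(self, X, train):
        K = self.kernel
        pad = K // 2
        Xp = np.pad(X, ((0, 0), (pad, K - 1 - pad), (0, 0)))
        self._Xp = Xp
        B, T, _ = X.shape
        out = np.tile(self.params["b"], (B, T, 1))
        for k in range(K):
            out += Xp[:, k : k + T] @ self.params["W"][k]
        return out

    def backward(self, dout):
        K = self.kernel
        pad = K // 2
        Xp = self._Xp
        B, T, C = dout.shape
        W = self.params["W"]
        dW = np.zeros_like(W)
        dXp = np.zeros_like(Xp)
        for k in range(K):
            seg = Xp[:, k : k + T]
            dW[k] = np.einsum("btd,btc->dc", seg, dout)
            dXp[:, k : k + T] += dout @ W[k].T
        self.grads = {"W": dW, "b": dout.sum(axis=(0, 1))}
        return dXp[:, pad : pad + T]


class ReLU(_Layer):
    def forward(self, X, train):
        self._mask = X > 0
        return X * self._mask

    def backward(self, dout):
        return dout * self._mask


class GlobalMaxPool(_Layer):
    """(B,T,C) -> (B,C) taking the max over time."""

    def forward(self, X, train):
        self._X_shape = X.shape
        self._arg = X.argmax(axis=1)
        return X.max(axis=1)

    def backward(self, dout):
        B, T, C = self._X_shape
        dX = np.zeros(self._X_shape)
        b_idx = np.arange(B)[:, None]
        c_idx = np.arange(C)[None, :]
        dX[b_idx, self._arg, c_idx] = dout
        return dX


class MeanPool(_Layer):
    """(B,T,C) -> (B,C) averaging over time."""

    def forward(self, X, train):
        self._T = X.shape[1]
        return X.mean(axis=1)

    def backward(self, dout):
        return np.repeat(dout[:, None, :] / self._T, self._T, axis=1)


# ---------------------------------------------------------------------------
# classifier


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    ridge_lambda: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SequenceClassifier:
    """Softmax sequence classifier over (B, T, D) spectra.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    units : int
        Hidden width (LSTM units / convolution channels).
    dropout : float
        Dropout rate between sequence layers.
    seed : int
        Drives initialisation, dropout masks and minibatch order.
    """

    n_classes = 2

    def __init__(
        self,
        family: str,
        units: int = 16,
        dropout: float = 0.1,
        seed: int = 0,
        kernel: int = 5,
        n_layers: int = 3,
    ):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        self.units = units
        self.dropout = dropout
        self.seed = seed
        self.kernel = kernel
        self.n_layers = n_layers
        self.layers: list[_Layer] | None = None

    # -- architecture ------------------------------------------------------

    def _build(self, d_in):
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 7)))
        drop_rng = np.random.default_rng(np.random.SeedSequence((self.seed, 11)))
        H = self.units
        layers: list[_Layer] = []
        if self.family == "conv1d":
            layers += [
                Conv1D(d_in, H, self.kernel, rng),
                ReLU(),
                Conv1D(H, H, self.kernel, rng),
                ReLU(),
                GlobalMaxPool(),
                Dense(H, self.n_classes, rng),
            ]
        else:
            cell = {
                "recurrent_sequence": LSTM,
                "bidirectional_recurrent": BiLSTM,
                "residual_bidirectional_recurrent": BiLSTM,
            }[self.family]
            residual = self.family == "residual_bidirectional_recurrent"
            d = d_in
            for li in range(self.n_layers):
                inner = cell(d, H, rng)
                if residual and d == H:
                    layers.append(Residual(inner))
                else:
                    layers.append(inner)
                d = H
                if li < self.n_layers - 1:
                    layers.append(Dropout(self.dropout, drop_rng))
                    layers.append(BatchNorm(H))
            layers += [MeanPool(), Dense(H, self.n_classes, rng)]
        self.layers = layers

    # -- forward / loss ----------------------------------------------------

    def _forward(self, X, train):
        out = X
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def loss_and_grads(self, X, y, lam):
        """Mean cross-entropy + ridge penalty, with gradients (for training
        and for numerical gradient checks)."""
        logits = self._forward(X, train=True)
        probs = _softmax(logits)
        B = X.shape[0]
        eps = 1e-12
        ce = -np.mean(np.log(probs[np.arange(B), y] + eps))
        reg = 0.0
        for layer in self.layers:
            for name in layer.regularized:
                reg += np.sum(layer.params[name] ** 2)
        loss = ce + lam * reg
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        dout = dlogits
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        for layer in self.layers:
            for name in layer.regularized:
                layer.grads[name] = layer.grads[name] + 2 * lam * layer.params[name]
        return loss, dout

    # -- training ----------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None, config: TrainConfig | None = None):
        """Train with Adam; early-stops on validation loss when given.

        Raises :class:`TrainingDiverged` if the loss becomes non-finite.
        """
        cfg = config or TrainConfig()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if self.layers is None:
            self._build(X.shape[-1])
        shuffle_rng = np.random.default_rng(np.random.SeedSequence((self.seed, 13)))

        # Adam state
        m_state, v_state = [], []
        for layer in self.layers:
            m_state.append({k: np.zeros_like(v) for k, v in layer.params.items()})
            v_state.append({k: np.zeros_like(v) for k, v in layer.params.items()})
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_params = None
        bad_epochs = 0
        self.history_: list[dict] = []

        n = X.shape[0]
        for epoch in range(cfg.max_epochs):
            order = shuffle_rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss, _ = self.loss_and_grads(X[idx], y[idx], cfg.ridge_lambda)
                if not np.isfinite(loss):
                    raise TrainingDiverged(
                        f"non-finite loss at epoch {epoch} "
                        f"(lr={cfg.learning_rate:g}, lambda={cfg.ridge_lambda:g}, "
                        f"batch={cfg.batch_size}, units={self.units}, "
                        f"dropout={self.dropout})"
                    )
                epoch_loss += loss
                n_batches += 1
                step += 1
                for layer, m_s, v_s in zip(self.layers, m_state, v_state):
                    for k, p in layer.params.items():
                        g = layer.grads[k]
                        m_s[k] = b1 * m_s[k] + (1 - b1) * g
                        v_s[k] = b2 * v_s[k] + (1 - b2) * g * g
                        mh = m_s[k] / (1 - b1**step)
                        vh = v_s[k] / (1 - b2**step)
                        layer.params[k] = p - cfg.learning_rate * mh / (np.sqrt(vh) + eps)
            rec = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
            if X_val is not None and len(X_val):
                val_loss = self._eval_loss(X_val, y_val, cfg.ridge_lambda)
                rec["val_loss"] = val_loss
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_params = [
                        {k: v.copy() for k, v in layer.params.items()}
                        for layer in self.layers
                    ]
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                if bad_epochs > cfg.patience:
                    self.history_.append(rec)
                    break
            self.history_.append(rec)
        if best_params is not None:
            for layer, p in zip(self.layers, best_params):
                layer.params = p
        return self

    def _eval_loss(self, X, y, lam):
        logits = self._forward(np.asarray(X, dtype=float), train=False)
        probs = _softmax(logits)
        ce = -np.mean(np.log(probs[np.arange(len(y)), np.asarray(y, dtype=int)] + 1e-12))
        reg = sum(
            np.sum(layer.params[name] ** 2)
            for layer in self.layers
            for name in layer.regularized
        )
        return float(ce + lam * reg)

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        if self.layers is None:
            raise RuntimeError("classifier is not fitted")
        return _softmax(self._forward(np.asarray(X, dtype=float), train=False))

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)
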