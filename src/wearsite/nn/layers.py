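"""Minimal numpy neural-network layers with exact analytic gradients.

Implements exactly what the package's two sequence classifiers need:
Dense (+ReLU), Dropout, Conv1D (valid padding, ReLU), MaxPool1D, LSTM
(optionally reversed / returning sequences), a Bidirectional wrapper, and
softmax cross-entropy.  Forward passes cache what backward needs; gradients
are verified against finite differences in the test suite.  All randomness
(initialization, dropout) flows through numpy Generators, so training is
bitwise-deterministic given a seed and a fixed thread count.
"""

from __future__ import annotations

import numpy as np


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class Layer:
    """Base: subclasses fill ``params`` and matching ``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, activation: str | None = None,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.activation = activation
        self.params = {"W": _glorot(rng, (in_dim, out_dim)),
                       "b": np.zeros(out_dim)}

    def forward(self, x, train, rng=None):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * self._mask
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Conv1D(Layer):
    """Temporal convolution, valid padding, stride 1, ReLU activation."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.in_channels = in_channels
        self.params = {"W": _glorot(rng, (kernel * in_channels, filters)),
                       "b": np.zeros(filters)}

    def forward(self, x, train, rng=None):
        B, T, C = x.shape
        K = self.kernel
        cols = np.lib.stride_tricks.sliding_window_view(x, K, axis=1)
        # (B, T-K+1, C, K) -> (B, T', K, C)
        cols = cols.transpose(0, 1, 3, 2)
        self._cols_shape = cols.shape
        self._x_shape = x.shape
        flat = cols.reshape(B * (T - K + 1), K * C)
        self._flat = flat
        z = flat @ self.params["W"] + self.params["b"]
        z = z.reshape(B, T - K + 1, -1)
        self._mask = z > 0
        return np.where(self._mask, z, 0.0)

    def backward(self, grad):
        grad = grad * self._mask
        B, Tp, F = grad.shape
        K, C = self.kernel, self.in_channels
        gflat = grad.reshape(B * Tp, F)
        self.grads["W"] = self._flat.T @ gflat
        self.grads["b"] = gflat.sum(axis=0)
        dcols = (gflat @ self.params["W"].T).reshape(B, Tp, K, C)
        dx = np.zeros(self._x_shape)
        for k in range(K):
            dx[:, k:k + Tp, :] += dcols[:, :, k, :]
        return dx


class MaxPool1D(Layer):
    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, train, rng=None):
        B, T, C = x.shape
        p = self.pool
        Tp = T // p
        self._x_shape = x.shape
        xr = x[:, :Tp * p].reshape(B, Tp, p, C)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        B, Tp, C = grad.shape
        p = self.pool
        dx = np.zeros((B, Tp, p, C))
        b, t, c = np.ogrid[:B, :Tp, :C]
        dx[b, t, self._arg, c] = grad
        out = np.zeros(self._x_shape)
        out[:, :Tp * p] = dx.reshape(B, Tp * p, C)
        return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


class LSTM(Layer):
    """Standard LSTM; gate order i, f, g, o; forget-gate bias starts at 1."""

    def __init__(self, in_dim: int, units: int, return_sequences: bool = False,
                 go_backwards: bool = False,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.units = units
        self.return_sequences = return_sequences
        self.go_backwards = go_backwards
        b = np.zeros(4 * units)
        b[units:2 * units] = 1.0
        self.params = {
            "Wx": _glorot(rng, (in_dim, 4 * units)),
            "Wh": np.concatenate(
                [_orthogonal(rng, units) for _ in range(4)], axis=1),
            "b": b,
        }

    def forward(self, x, train, rng=None):
        if self.go_backwards:
            x = x[:, ::-1]
        B, T, D = x.shape
        u = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        self._x = x
        self._gates = np.empty((T, B, 4 * u))
        self._c = np.empty((T, B, u))
        self._tanh_c = np.empty((T, B, u))
        self._h_prev = np.empty((T, B, u))
        hs = np.empty((B, T, u))
        xz = x.reshape(B * T, D) @ Wx  # precompute input contribution
        xz = xz.reshape(B, T, 4 * u)
        for t in range(T):
            self._h_prev[t] = h
            z = xz[:, t] + h @ Wh + b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            self._gates[t, :, :u] = i
            self._gates[t, :, u:2 * u] = f
            self._gates[t, :, 2 * u:3 * u] = g
            self._gates[t, :, 3 * u:] = o
            self._c[t] = c
            self._tanh_c[t] = tc
            hs[:, t] = h
        self._hs = hs
        if self.return_sequences:
            return hs[:, ::-1] if self.go_backwards else hs
        return hs[:, -1]

    def backward(self, grad):
        x = self._x
        B, T, D = x.shape
        u = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        if self.return_sequences:
            gseq = grad[:, ::-1] if self.go_backwards else grad
        else:
            gseq = None
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * u)
        dh_next = np.zeros((B, u)) if gseq is not None else grad.copy()
        dc_next = np.zeros((B, u))
        dx = np.empty_like(x)
        dzs = np.empty((T, B, 4 * u))
        for t in range(T - 1, -1, -1):
            dh = dh_next if gseq is None else dh_next + gseq[:, t]
            i = self._gates[t, :, :u]
            f = self._gates[t, :, u:2 * u]
            g = self._gates[t, :, 2 * u:3 * u]
            o = self._gates[t, :, 3 * u:]
            tc = self._tanh_c[t]
            c_prev = self._c[t - 1] if t > 0 else np.zeros((B, u))
            dc = dc_next + dh * o * (1.0 - tc ** 2)
            do = dh * tc
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.empty((B, 4 * u))
            dz[:, :u] = di * i * (1.0 - i)
            dz[:, u:2 * u] = df * f * (1.0 - f)
            dz[:, 2 * u:3 * u] = dg * (1.0 - g ** 2)
            dz[:, 3 * u:] = do * o * (1.0 - o)
            dzs[t] = dz
            dWh += self._h_prev[t].T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ Wh.T
            dc_next = dc * f
        # input-side gradients in one batched product
        dz_all = dzs.transpose(1, 0, 2).reshape(B * T, 4 * u)
        dWx = x.reshape(B * T, D).T @ dz_all
        dx = (dz_all @ Wx.T).reshape(B, T, D)
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx[:, ::-1] if self.go_backwards else dx


class Bidirectional(Layer):
    """Two LSTMs over opposite time directions, features concatenated."""

    def __init__(self, in_dim: int, units: int, return_sequences: bool = True,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fwd = LSTM(in_dim, units, return_sequences=return_sequences,
                        go_backwards=False, rng=rng)
        self.bwd = LSTM(in_dim, units, return_sequences=return_sequences,
                        go_backwards=True, rng=rng)
        self.units = units
        for k, v in self.fwd.params.items():
            self.params[f"fwd_{k}"] = v
        for k, v in self.bwd.params.items():
            self.params[f"bwd_{k}"] = v

    def forward(self, x, train, rng=None):
        return np.concatenate([self.fwd.forward(x, train),
                               self.bwd.forward(x, train)], axis=-1)

    def backward(self, grad):
        u = self.units
        dx = self.fwd.backward(grad[..., :u]) + self.bwd.backward(grad[..., u:])
        for k, v in self.fwd.grads.items():
            self.grads[f"fwd_{k}"] = v
        for k, v in self.bwd.grads.items():
            self.grads[f"bwd_{k}"] = v
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -float(np.log(p[np.arange(n), labels] + eps).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adaptive-moment optimizer over a list of layers."""

    def __init__(self, layers: list[Layer], learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
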