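"""Neural-network building blocks with explicit forward/backward passes.

All layers operate on float64 numpy arrays and cache what the backward pass
needs.  The GRU recurrence (the only sequential bottleneck) is JIT-compiled
with numba; the input projections and all weight-gradient contractions are
batched numpy matmuls outside the loop.  Every backward pass is verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["Conv1d", "BatchNorm1d", "Swish", "AvgPool1d", "Dense", "GRU",
           "softmax", "softmax_cross_entropy"]


class Layer:
    """Minimal parameterized-layer protocol."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv1d(Layer):
    """1-D convolution, stride 1, zero-padded to preserve length."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError("kernel size must be a positive odd integer")
        scale = np.sqrt(2.0 / (in_channels * kernel))
        self.kernel = kernel
        self.params = {
            "W": scale * rng.standard_normal((out_channels, in_channels, kernel)),
            "b": np.zeros(out_channels),
        }

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, length = x.shape
        k = self.kernel
        pad = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        cols = np.empty((n, c, k, length))
        for j in range(k):
            cols[:, :, j, :] = xp[:, :, j:j + length]
        self._cols = cols
        W = self.params["W"]
        y = np.matmul(W.reshape(W.shape[0], c * k), cols.reshape(n, c * k, length))
        return y + self.params["b"][:, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        o, c, k = W.shape
        n, _, length = gy.shape
        pad = (k - 1) // 2
        cols = self._cols
        self.grads["W"] = np.tensordot(gy, cols, axes=([0, 2], [0, 3]))
        self.grads["b"] = gy.sum(axis=(0, 2))
        dcols = np.matmul(W.reshape(o, c * k).T, gy).reshape(n, c, k, length)
        dxp = np.zeros((n, c, length + 2 * pad))
        for j in range(k):
            dxp[:, :, j:j + length] += dcols[:, :, j, :]
        return dxp[:, :, pad:pad + length]


class BatchNorm1d(Layer):
    """Batch normalization over (batch, position) per channel."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None]) * inv[:, None]
        self._cache = (xhat, inv, training, x.shape[0] * x.shape[2])
        return self.params["gamma"][:, None] * xhat + self.params["beta"][:, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv, training, m = self._cache
        gamma = self.params["gamma"]
        self.grads["gamma"] = (gy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = gy.sum(axis=(0, 2))
        gxhat = gy * gamma[:, None]
        if not training:
            return gxhat * inv[:, None]
        return (inv[:, None] / m) * (
            m * gxhat
            - gxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=(0, 2), keepdims=True)
        )


@njit(cache=True)
def _swish_forward_kernel(x):
    sig = 1.0 / (1.0 + np.exp(-x))
    return x * sig, sig


@njit(cache=True)
def _swish_backward_kernel(gy, x, sig):
    return gy * (sig * (1.0 + x * (1.0 - sig)))


class Swish(Layer):
    """x * sigmoid(x)."""

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x)
        y, sig = _swish_forward_kernel(x)
        self._cache = (x, sig)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, sig = self._cache
        return _swish_backward_kernel(np.ascontiguousarray(gy), x, sig)


class AvgPool1d(Layer):
    """Segment-average pooling along the position axis.

    Segments are ``pool`` points wide (the trailing segment may be shorter);
    with ``pool=1`` this is the identity.
    """

    def __init__(self, pool: int):
        super().__init__()
        if pool < 1:
            raise ValueError("pool must be >= 1")
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        length = x.shape[2]
        starts = np.arange(0, length, self.pool)
        self._counts = np.diff(np.append(starts, length))
        return np.add.reduceat(x, starts, axis=2) / self._counts

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.repeat(gy / self._counts, self._counts, axis=2)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(1.0 / in_features)
        self.params = {
            "W": scale * rng.standard_normal((in_features, out_features)),
            "b": np.zeros(out_features),
        }

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ gy
        self.grads["b"] = gy.sum(axis=0)
        return gy @ self.params["W"].T


@njit(cache=True)
def _gru_forward_kernel(xW, U):
    L, N, H3 = xW.shape
    H = H3 // 3
    h_seq = np.zeros((L + 1, N, H))
    z_s = np.empty((L, N, H))
    r_s = np.empty((L, N, H))
    n_s = np.empty((L, N, H))
    un_s = np.empty((L, N, H))
    for t in range(L):
        h = h_seq[t]
        u = np.dot(h, U)
        z = 1.0 / (1.0 + np.exp(-(xW[t, :, :H] + u[:, :H])))
        r = 1.0 / (1.0 + np.exp(-(xW[t, :, H:2 * H] + u[:, H:2 * H])))
        un = u[:, 2 * H:]
        n = np.tanh(xW[t, :, 2 * H:] + r * un)
        z_s[t] = z
        r_s[t] = r
        n_s[t] = n
        un_s[t] = un
        h_seq[t + 1] = (1.0 - z) * n + z * h
    return h_seq, z_s, r_s, n_s, un_s


@njit(cache=True)
def _gru_backward_kernel(gH, h_seq, z_s, r_s, n_s, un_s, UT):
    L, N, H = gH.shape
    dxW = np.empty((L, N, 3 * H))
    dun_s = np.empty((L, N, H))
    du = np.empty((N, 3 * H))
    dh = np.zeros((N, H))
    for t in range(L - 1, -1, -1):
        dh = dh + gH[t]
        z = z_s[t]
        r = r_s[t]
        n = n_s[t]
        un = un_s[t]
        h_prev = h_seq[t]
        dn = dh * (1.0 - z)
        dz = dh * (h_prev - n)
        dh_prev = dh * z
        dpre_n = dn * (1.0 - n * n)
        dun = dpre_n * r
        dr = dpre_n * un
        dpre_z = dz * z * (1.0 - z)
        dpre_r = dr * r * (1.0 - r)
        dxW[t, :, :H] = dpre_z
        dxW[t, :, H:2 * H] = dpre_r
        dxW[t, :, 2 * H:] = dpre_n
        dun_s[t] = dun
        du[:, :H] = dpre_z
        du[:, H:2 * H] = dpre_r
        du[:, 2 * H:] = dun
        dh = dh_prev + np.dot(du, UT)
    return dxW, dun_s


class GRU(Layer):
    """Gated recurrent unit over a (batch, time, features) sequence.

    Gate convention (update z, reset r, candidate n):
        z = sigmoid(x Wz + h Uz + bz)
        r = sigmoid(x Wr + h Ur + br)
        n = tanh(x Wn + r * (h Un) + bn)
        h' = (1 - z) * n + z * h
    Returns the full hidden sequence; the initial state is zero.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        s = np.sqrt(1.0 / hidden_size)
        self.params = {
            "W": s * rng.uniform(-1, 1, (input_size, 3 * hidden_size)),
            "U": s * rng.uniform(-1, 1, (hidden_size, 3 * hidden_size)),
            "b": np.zeros(3 * hidden_size),
        }

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, length, _ = x.shape
        xW = x.reshape(n * length, -1) @ self.params["W"] + self.params["b"]
        xW = np.ascontiguousarray(
            xW.reshape(n, length, -1).transpose(1, 0, 2))
        h_seq, z_s, r_s, n_s, un_s = _gru_forward_kernel(xW, self.params["U"])
        self._cache = (x, h_seq, z_s, r_s, n_s, un_s)
        return np.ascontiguousarray(h_seq[1:].transpose(1, 0, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, h_seq, z_s, r_s, n_s, un_s = self._cache
        n, length, _ = x.shape
        gH = np.ascontiguousarray(gy.transpose(1, 0, 2))
        UT = np.ascontiguousarray(self.params["U"].T)
        dxW, dun_s = _gru_backward_kernel(gH, h_seq, z_s, r_s, n_s, un_s, UT)
        h = self.hidden_size
        du_all = np.concatenate((dxW[:, :, :2 * h], dun_s), axis=2)
        self.grads["U"] = np.tensordot(h_seq[:-1], du_all, axes=([0, 1], [0, 1]))
        dxW_flat = dxW.transpose(1, 0, 2).reshape(n * length, -1)
        x_flat = x.reshape(n * length, -1)
        self.grads["W"] = x_flat.T @ dxW_flat
        self.grads["b"] = dxW_flat.sum(axis=0)
        return (dxW_flat @ self.params["W"].T).reshape(n, length, -1)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy of integer targets; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), targets], 1e-300, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return float(loss), dlogits / n
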