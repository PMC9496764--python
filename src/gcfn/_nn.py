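"""Minimal numpy neural-network layers with manual backpropagation.

Only what the fusion classifier needs: a full-height 2-D convolution
(which collapses to a per-column matrix product), ReLU, width-wise max
pooling, dense layers, inverted dropout, and a gated-recurrent-unit layer
in the two-bias ("reset-after") convention, where each gate carries both an
input-side and a recurrent-side bias:

    r_t = sigmoid(x_t Wx_r + bx_r + h_{t-1} Wh_r + bh_r)
    z_t = sigmoid(x_t Wx_z + bx_z + h_{t-1} Wh_z + bh_z)
    g_t = tanh(x_t Wx_g + bx_g + r_t * (h_{t-1} Wh_g + bh_g))
    h_t = (1 - z_t) * h_{t-1} + z_t * g_t

so a layer with ``u`` units on ``i`` inputs has ``3*(u*(i+u) + 2*u)``
trainable parameters.  Layers own their parameters and accumulate
gradients on ``backward``; the Adam optimizer updates them in place.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid", "glorot_uniform", "orthogonal",
    "Dense", "ReLU", "Dropout", "ConvFullHeight", "MaxPoolWidth", "GRULayer",
    "Adam", "softmax",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class Layer:
    """Base: parameter/gradient bookkeeping shared by all layers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    @property
    def n_params(self) -> int:
        return sum(int(v.size) for v in self.params.values())


class Dense(Layer):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int) -> None:
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.params = {
            "W": glorot_uniform(rng, (n_in, n_out), n_in, n_out),
            "b": np.zeros(n_out),
        }
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must lie in [0, 1), got {p}")
        self.p = p

    def forward(self, x: np.ndarray, *, train: bool, rng: np.random.Generator) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class ConvFullHeight(Layer):
    """2-D convolution with an (H x 1) kernel on an (H x W) input.

    The kernel spans the full input height, so with 'valid' padding the
    output height collapses to 1 and each output column is an inner product
    of the kernel with the corresponding input column — a matrix product.
    Input (n, H, W) -> output (n, filters, W).
    """

    def __init__(self, rng: np.random.Generator, height: int, n_filters: int) -> None:
        super().__init__()
        self.height, self.n_filters = height, n_filters
        self.params = {
            "W": glorot_uniform(rng, (n_filters, height), height, n_filters),
            "b": np.zeros(n_filters),
        }
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("fh,nhw->nfw", self.params["W"], x, optimize=True) \
            + self.params["b"][None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += np.einsum("nfw,nhw->fh", dout, self._x, optimize=True)
        self.grads["b"] += dout.sum(axis=(0, 2))
        return np.einsum("fh,nfw->nhw", self.params["W"], dout, optimize=True)


class MaxPoolWidth(Layer):
    """Max pooling along the width axis, floor semantics, no padding."""

    def __init__(self, pool: int = 3, stride: int = 3) -> None:
        super().__init__()
        if pool != stride:
            raise ValueError("only pool == stride is supported")
        self.pool = pool

    def out_width(self, w: int) -> int:
        return w // self.pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, f, w = x.shape
        wo = self.out_width(w)
        self._shape = x.shape
        windows = x[..., : wo * self.pool].reshape(n, f, wo, self.pool)
        self._argmax = windows.argmax(axis=-1)
        return windows.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, w = self._shape
        wo = dout.shape[-1]
        dwin = np.zeros((n, f, wo, self.pool))
        idx = np.indices((n, f, wo))
        dwin[idx[0], idx[1], idx[2], self._argmax] = dout
        dx = np.zeros(self._shape)
        dx[..., : wo * self.pool] = dwin.reshape(n, f, wo * self.pool)
        return dx


class GRULayer(Layer):
    """Two-bias (reset-after) GRU over a full sequence.

    Input (n, T, n_in); returns the full state sequence (n, T, units) when
    ``return_sequences`` else the final state (n, units).  Gate blocks are
    ordered [reset, update, candidate] along the last parameter axis.
    """

    def __init__(self, rng: np.random.Generator, n_in: int, units: int,
                 return_sequences: bool = False) -> None:
        super().__init__()
        self.n_in, self.units = n_in, units
        self.return_sequences = return_sequences
        wh = np.concatenate([orthogonal(rng, units) for _ in range(3)], axis=1)
        self.params = {
            "Wx": glorot_uniform(rng, (n_in, 3 * units), n_in, units),
            "Wh": wh,
            "bx": np.zeros(3 * units),
            "bh": np.zeros(3 * units),
        }
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, T, _ = x.shape
        u = self.units
        Wh = self.params["Wh"]
        xg = x @ self.params["Wx"] + self.params["bx"]  # (n, T, 3u)
        h = np.zeros((n, u))
        self._x, self._xg = x, xg
        self._h_prev = np.empty((T, n, u))
        self._r = np.empty((T, n, u))
        self._z = np.empty((T, n, u))
        self._g = np.empty((T, n, u))
        self._hg_g = np.empty((T, n, u))
        seq = np.empty((n, T, u)) if self.return_sequences else None
        for t in range(T):
            hg = h @ Wh + self.params["bh"]
            r = sigmoid(xg[:, t, :u] + hg[:, :u])
            z = sigmoid(xg[:, t, u:2 * u] + hg[:, u:2 * u])
            g = np.tanh(xg[:, t, 2 * u:] + r * hg[:, 2 * u:])
            self._h_prev[t], self._r[t], self._z[t] = h, r, z
            self._g[t], self._hg_g[t] = g, hg[:, 2 * u:]
            h = (1.0 - z) * h + z * g
            if seq is not None:
                seq[:, t] = h
        self._h_last = h
        return seq if self.return_sequences else h

    def backward(self, dout: np.ndarray, *, need_dx: bool = True) -> np.ndarray | None:
        """Backpropagate; ``dout`` is (n, T, units) for sequence output or
        (n, units) for final-state output.  Returns d(input) if requested."""
        x, xg = self._x, self._xg
        n, T, _ = x.shape
        u = self.units
        Wh = self.params["Wh"]
        dWh = self.grads["Wh"]
        dbh = self.grads["bh"]
        dxg = np.zeros_like(xg)
        dh = np.zeros((n, u))
        for t in range(T - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dout[:, t]
            elif t == T - 1:
                dh = dh + dout
            h_prev, r, z, g, hg_g = (self._h_prev[t], self._r[t], self._z[t],
                                     self._g[t], self._hg_g[t])
            dz = dh * (g - h_prev)
            dg = dh * z
            dh_prev = dh * (1.0 - z)
            da_g = dg * (1.0 - g * g)          # pre-tanh
            dr = da_g * hg_g
            dhg_g = da_g * r
            da_r = dr * r * (1.0 - r)          # pre-sigmoid
            da_z = dz * z * (1.0 - z)
            dxg[:, t, :u] = da_r
            dxg[:, t, u:2 * u] = da_z
            dxg[:, t, 2 * u:] = da_g
            dhg = np.concatenate([da_r, da_z, dhg_g], axis=1)
            dWh += h_prev.T @ dhg
            dbh += dhg.sum(axis=0)
            dh = dh_prev + dhg @ Wh.T
        self.grads["Wx"] += np.einsum("nti,ntj->ij", x, dxg, optimize=True)
        self.grads["bx"] += dxg.sum(axis=(0, 1))
        if need_dx:
            return dxg @ self.params["Wx"].T
        return None


class Adam:
    """Adam optimizer over a list of layers' parameters."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.beta1 * m[k] + (1.0 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1.0 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
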