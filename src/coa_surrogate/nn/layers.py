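"""Neural-network layers with explicit forward/backward passes.

Tensor layout is channels-last throughout: sequences are (B, T, C) and
volumes are (B, D, H, W, C).  Each layer owns its parameters as ``Param``
objects (value + accumulated gradient) and caches whatever the backward
pass needs during ``forward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array and its gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: subclasses set ``self.params`` (dict name -> Param)."""

    def __init__(self):
        self.params: dict[str, Param] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def zero_grad(self):
        for p in self.params.values():
            p.grad[...] = 0.0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class Dense(Layer):
    """Affine map on the last axis: y = x @ W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.params = {
            "W": Param(glorot(rng, (n_in, n_out), n_in, n_out, dtype)),
            "b": Param(np.zeros(n_out, dtype=dtype)),
        }

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"].value + self.params["b"].value

    def backward(self, dout):
        x2 = self._x.reshape(-1, self.n_in)
        d2 = dout.reshape(-1, self.n_out)
        self.params["W"].grad += x2.T @ d2
        self.params["b"].grad += d2.sum(axis=0)
        return dout @ self.params["W"].value.T


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.3):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, dout):
        return np.where(self._neg, self.slope * dout, dout)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._neg = x < 0
        return np.where(self._neg, 0.0, x)

    def backward(self, dout):
        return np.where(self._neg, 0.0, dout)


class _LSTMDirection:
    """One direction of an LSTM; gate order [input, forget, cell, output]."""

    def __init__(self, n_in, n_hidden, rng, dtype):
        H = n_hidden
        self.n_in, self.H = n_in, H
        self.Wx = Param(glorot(rng, (n_in, 4 * H), n_in, 4 * H, dtype))
        self.Wh = Param(glorot(rng, (H, 4 * H), H, 4 * H, dtype))
        self.b = Param(np.zeros(4 * H, dtype=dtype))
        # forget-gate bias of 1: standard initialisation for gradient flow
        self.b.value[H : 2 * H] = 1.0

    def forward(self, x):
        B, T, _ = x.shape
        H = self.H
        xp = x.reshape(B * T, self.n_in) @ self.Wx.value + self.b.value
        xp = xp.reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        self._x = x
        self._cache = []
        hs = np.empty((B, T, H), dtype=x.dtype)
        Wh = self.Wh.value
        for t in range(T):
            z = xp[:, t] + h @ Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev, h_prev = c, h
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            self._cache.append((i, f, g, o, c_prev, h_prev, tc))
        return hs

    def backward(self, dhs):
        x = self._x
        B, T, _ = x.shape
        H = self.H
        Wh = self.Wh.value
        dh_next = np.zeros((B, H), dtype=x.dtype)
        dc_next = np.zeros((B, H), dtype=x.dtype)
        dz_all = np.empty((B, T, 4 * H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = self._cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dz_all[:, t] = dz
            self.Wh.grad += h_prev.T @ dz
            dh_next = dz @ Wh.T
            dc_next = dc * f
        dz2 = dz_all.reshape(B * T, 4 * H)
        self.Wx.grad += x.reshape(B * T, self.n_in).T @ dz2
        self.b.grad += dz2.sum(axis=0)
        return dz_all @ self.Wx.value.T


class BiLSTM(Layer):
    """Bidirectional LSTM; forward and backward outputs concatenated (B, T, 2H)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.fwd = _LSTMDirection(n_in, n_hidden, rng, dtype)
        self.bwd = _LSTMDirection(n_in, n_hidden, rng, dtype)
        self.params = {
            "fwd_Wx": self.fwd.Wx, "fwd_Wh": self.fwd.Wh, "fwd_b": self.fwd.b,
            "bwd_Wx": self.bwd.Wx, "bwd_Wh": self.bwd.Wh, "bwd_b": self.bwd.b,
        }
        self.n_hidden = n_hidden

    def forward(self, x, train=True):
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dout):
        H = self.n_hidden
        dxf = self.fwd.backward(np.ascontiguousarray(dout[:, :, :H]))
        dxb = self.bwd.backward(np.ascontiguousarray(dout[:, ::-1, H:]))[:, ::-1]
        return dxf + dxb


def _conv3d_corr(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Valid correlation of (B, D, H, W, Cin) with (k, k, k, Cin, Cout)."""
    k = W.shape[0]
    win = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
    # win: (B, D', H', W', Cin, k, k, k)
    return np.einsum("bdhwcijk,ijkco->bdhwo", win, W, optimize=True)


class Conv3D(Layer):
    """3x3x3 (or kxkxk) same-padded 3D convolution, stride 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3, dtype=np.float32):
        super().__init__()
        self.k = k
        fan_in = c_in * k**3
        self.params = {
            "W": Param(glorot(rng, (k, k, k, c_in, c_out), fan_in, c_out * k**3, dtype)),
            "b": Param(np.zeros(c_out, dtype=dtype)),
        }

    def forward(self, x, train=True):
        p = self.k // 2
        self._xp = np.pad(x, [(0, 0), (p, p), (p, p), (p, p), (0, 0)])
        return _conv3d_corr(self._xp, self.params["W"].value) + self.params["b"].value

    def backward(self, dout):
        k, p = self.k, self.k // 2
        W = self.params["W"].value
        win = sliding_window_view(self._xp, (k, k, k), axis=(1, 2, 3))
        self.params["W"].grad += np.einsum(
            "bdhwcijk,bdhwo->ijkco", win, dout, optimize=True
        )
        self.params["b"].grad += dout.sum(axis=(0, 1, 2, 3))
        # full correlation of dout with the spatially flipped, transposed kernel
        dpad = np.pad(dout, [(0, 0), (p, p), (p, p), (p, p), (0, 0)])
        Wt = W[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)
        return _conv3d_corr(dpad, np.ascontiguousarray(Wt))


class MaxPool3D(Layer):
    """2x2x2 max pooling, stride 2 (non-overlapping)."""

    def forward(self, x, train=True):
        B, D, H, W, C = x.shape
        xr = x.reshape(B, D // 2, 2, H // 2, 2, W // 2, 2, C)
        xr = xr.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(B, D // 2, H // 2, W // 2, C, 8)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        B, D, H, W, C = self._shape
        dr = np.zeros((B, D // 2, H // 2, W // 2, C, 8), dtype=dout.dtype)
        np.put_along_axis(dr, self._arg[..., None], dout[..., None], axis=-1)
        dr = dr.reshape(B, D // 2, H // 2, W // 2, C, 2, 2, 2)
        dr = dr.transpose(0, 1, 5, 2, 6, 3, 7, 4)
        return dr.reshape(B, D, H, W, C)


class ConvTranspose3D(Layer):
    """2x2x2 transpose convolution with stride 2 (no overlap): learnable upsampling."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.params = {
            "W": Param(glorot(rng, (c_in, 2, 2, 2, c_out), c_in, c_out * 8, dtype)),
            "b": Param(np.zeros(c_out, dtype=dtype)),
        }

    def forward(self, x, train=True):
        self._x = x
        B, D, H, W, C = x.shape
        y = np.einsum("bdhwc,cijko->bdihjwko", x, self.params["W"].value, optimize=True)
        return y.reshape(B, 2 * D, 2 * H, 2 * W, -1) + self.params["b"].value

    def backward(self, dout):
        x = self._x
        B, D, H, W, C = x.shape
        co = dout.shape[-1]
        d6 = dout.reshape(B, D, 2, H, 2, W, 2, co)
        self.params["W"].grad += np.einsum(
            "bdhwc,bdihjwko->cijko", x, d6, optimize=True
        )
        self.params["b"].grad += dout.sum(axis=(0, 1, 2, 3))
        return np.einsum("bdihjwko,cijko->bdhwc", d6, self.params["W"].value, optimize=True)


class BatchNorm(Layer):
    """Batch normalisation over all axes except the last (channel) axis."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.params = {
            "gamma": Param(np.ones(channels, dtype=dtype)),
            "beta": Param(np.zeros(channels, dtype=dtype)),
        }
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x, train=True):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv
        self._n = x.size // x.shape[-1]
        self._train = train
        return self.params["gamma"].value * self._xhat + self.params["beta"].value

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        gamma = self.params["gamma"].value
        self.params["gamma"].grad += (dout * self._xhat).sum(axis=axes)
        self.params["beta"].grad += dout.sum(axis=axes)
        dxhat = dout * gamma
        if not self._train:
            return dxhat * self._inv
        n = self._n
        return (
            self._inv
            / n
            * (n * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes))
        )
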