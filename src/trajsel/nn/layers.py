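"""Minimal feed-forward / recurrent layers on numpy arrays.

The layers implement exactly what the trajectory classifiers need: valid
(unpadded) convolutions, non-overlapping max pooling, dense heads, inverted
dropout and a standard LSTM cell, each with an analytic backward pass.
Activations are fused into Conv/Dense layers (Keras-style); the final sigmoid
of a classifier is kept as its own layer so that saliency code can read the
pre-sigmoid score.

Shape conventions: 1-D signals are ``(N, T, C)``, 2-D images ``(N, H, W, C)``,
flat features ``(N, F)``. All parameters and activations are float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32

_ACTIVATIONS = ("relu", "tanh", "sigmoid", None)


def _sigmoid(x):
    # numerically stable in float32
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot_uniform(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base layer: parameters in ``self.params``, gradients in ``self.grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.built = False

    def build(self, input_shape, rng):
        """Allocate parameters for ``input_shape`` (no batch axis); return output shape."""
        self.built = True
        return input_shape

    def forward(self, x, training=False):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class _Activatable(Layer):
    def __init__(self, activation):
        super().__init__()
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation

    def _apply_activation(self, z):
        if self.activation == "relu":
            a = np.maximum(z, 0.0)
        elif self.activation == "tanh":
            a = np.tanh(z)
        elif self.activation == "sigmoid":
            a = _sigmoid(z)
        else:
            a = z
        self._act_out = a
        return a

    def _activation_backward(self, dy):
        if self.activation == "relu":
            return dy * (self._act_out > 0)
        if self.activation == "tanh":
            return dy * (1.0 - self._act_out**2)
        if self.activation == "sigmoid":
            return dy * self._act_out * (1.0 - self._act_out)
        return dy


class Dense(_Activatable):
    def __init__(self, units, activation=None):
        super().__init__(activation)
        self.units = units

    def build(self, input_shape, rng):
        (fan_in,) = input_shape
        self.params["W"] = _glorot_uniform(rng, (fan_in, self.units), fan_in, self.units)
        self.params["b"] = np.zeros(self.units, dtype=DTYPE)
        self.built = True
        return (self.units,)

    def forward(self, x, training=False):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        self._z = z
        return self._apply_activation(z)

    def backward(self, dy):
        dz = self._activation_backward(dy)
        self.grads["W"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T


class Sigmoid(Layer):
    """Standalone output sigmoid (kept separate so the logit is addressable)."""

    def forward(self, x, training=False):
        self._out = _sigmoid(x)
        return self._out

    def backward(self, dy):
        return dy * self._out * (1.0 - self._out)


class Conv1D(_Activatable):
    """Valid (unpadded) temporal convolution, stride 1."""

    def __init__(self, filters, kernel_size, activation="relu"):
        super().__init__(activation)
        self.filters = filters
        self.kernel_size = kernel_size

    def build(self, input_shape, rng):
        t, c = input_shape
        k, f = self.kernel_size, self.filters
        if t < k:
            raise ValueError(f"input length {t} shorter than kernel {k}")
        self.in_channels = c
        self.params["W"] = _glorot_uniform(rng, (k * c, f), k * c, k * f)
        self.params["b"] = np.zeros(f, dtype=DTYPE)
        self.built = True
        return (t - k + 1, f)

    def forward(self, x, training=False):
        n, t, c = x.shape
        k = self.kernel_size
        # (N, L, C, k) -> (N, L, k, C) -> (N, L, k*C); W rows ordered (offset, channel)
        win = sliding_window_view(x, k, axis=1)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(n, t - k + 1, k * c)
        self._cols = cols
        self._in_len = t
        z = cols @ self.params["W"] + self.params["b"]
        return self._apply_activation(z)

    def backward(self, dy):
        dz = self._activation_backward(dy)
        n, l, f = dz.shape
        k, c = self.kernel_size, self.in_channels
        cols2 = self._cols.reshape(-1, k * c)
        dz2 = dz.reshape(-1, f)
        self.grads["W"] = cols2.T @ dz2
        self.grads["b"] = dz2.sum(axis=0)
        dcols = (dz2 @ self.params["W"].T).reshape(n, l, k, c)
        dx = np.zeros((n, self._in_len, c), dtype=DTYPE)
        for i in range(k):
            dx[:, i : i + l, :] += dcols[:, :, i, :]
        return dx


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; a trailing remainder is dropped."""

    def __init__(self, pool_size):
        super().__init__()
        self.pool_size = pool_size

    def build(self, input_shape, rng):
        t, c = input_shape
        self.built = True
        return (t // self.pool_size, c)

    def forward(self, x, training=False):
        n, t, c = x.shape
        p = self.pool_size
        lp = t // p
        xt = x[:, : lp * p].reshape(n, lp, p, c)
        self._idx = xt.argmax(axis=2)
        self._in_shape = x.shape
        return np.take_along_axis(xt, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        n, t, c = self._in_shape
        p = self.pool_size
        lp = t // p
        dxt = np.zeros((n, lp, p, c), dtype=DTYPE)
        np.put_along_axis(dxt, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((n, t, c), dtype=DTYPE)
        dx[:, : lp * p] = dxt.reshape(n, lp * p, c)
        return dx


class GlobalMaxPool1D(Layer):
    def build(self, input_shape, rng):
        t, c = input_shape
        self.built = True
        return (c,)

    def forward(self, x, training=False):
        self._idx = x.argmax(axis=1)
        self._in_shape = x.shape
        return np.take_along_axis(x, self._idx[:, None, :], axis=1)[:, 0, :]

    def backward(self, dy):
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        np.put_along_axis(dx, self._idx[:, None, :], dy[:, None, :], axis=1)
        return dx


class Conv2D(_Activatable):
    """Valid (unpadded) 2-D convolution, stride 1, NHWC layout."""

    def __init__(self, filters, kernel_size, activation="relu"):
        super().__init__(activation)
        self.filters = filters
        self.kh, self.kw = kernel_size

    def build(self, input_shape, rng):
        h, w, c = input_shape
        if h < self.kh or w < self.kw:
            raise ValueError(f"input {h}x{w} smaller than kernel {self.kh}x{self.kw}")
        self.in_channels = c
        fan_in = self.kh * self.kw * c
        self.params["W"] = _glorot_uniform(
            rng, (fan_in, self.filters), fan_in, self.kh * self.kw * self.filters
        )
        self.params["b"] = np.zeros(self.filters, dtype=DTYPE)
        self.built = True
        return (h - self.kh + 1, w - self.kw + 1, self.filters)

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        kh, kw = self.kh, self.kw
        ho, wo = h - kh + 1, w - kw + 1
        win = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (N, Ho, Wo, C, kh, kw)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n, ho, wo, kh * kw * c
        )
        self._cols = cols
        self._in_shape = x.shape
        z = cols @ self.params["W"] + self.params["b"]
        return self._apply_activation(z)

    def backward(self, dy):
        dz = self._activation_backward(dy)
        n, ho, wo, f = dz.shape
        kh, kw, c = self.kh, self.kw, self.in_channels
        cols2 = self._cols.reshape(-1, kh * kw * c)
        dz2 = dz.reshape(-1, f)
        self.grads["W"] = cols2.T @ dz2
        self.grads["b"] = dz2.sum(axis=0)
        dcols = (dz2 @ self.params["W"].T).reshape(n, ho, wo, kh, kw, c)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        for a in range(kh):
            for b in range(kw):
                dx[:, a : a + ho, b : b + wo, :] += dcols[:, :, :, a, b, :]
        return dx


class MaxPool2D(Layer):
    def __init__(self, pool_size):
        super().__init__()
        self.ph, self.pw = pool_size

    def build(self, input_shape, rng):
        h, w, c = input_shape
        self.built = True
        return (h // self.ph, w // self.pw, c)

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        ph, pw = self.ph, self.pw
        ho, wo = h // ph, w // pw
        xt = x[:, : ho * ph, : wo * pw].reshape(n, ho, ph, wo, pw, c)
        xt = np.ascontiguousarray(xt.transpose(0, 1, 3, 2, 4, 5)).reshape(
            n, ho, wo, ph * pw, c
        )
        self._idx = xt.argmax(axis=3)
        self._in_shape = x.shape
        return np.take_along_axis(xt, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy):
        n, h, w, c = self._in_shape
        ph, pw = self.ph, self.pw
        ho, wo = h // ph, w // pw
        dxt = np.zeros((n, ho, wo, ph * pw, c), dtype=DTYPE)
        np.put_along_axis(dxt, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dxt = dxt.reshape(n, ho, wo, ph, pw, c).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros((n, h, w, c), dtype=DTYPE)
        dx[:, : ho * ph, : wo * pw] = dxt.reshape(n, ho * ph, wo * pw, c)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = None  # assigned at build time from the model seed

    def build(self, input_shape, rng):
        self.rng = np.random.default_rng(rng.integers(2**31))
        self.built = True
        return input_shape

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def build(self, input_shape, rng):
        self._out = int(np.prod(input_shape))
        self.built = True
        return (self._out,)

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class LSTM(Layer):
    """Standard LSTM (gate order i, f, g, o) with forget-gate bias 1.

    ``return_sequences=False`` emits the final hidden state, which doubles as
    the window embedding used by the semi-supervised classifier.
    """

    def __init__(self, units, return_sequences=False):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences

    def build(self, input_shape, rng):
        t, c = input_shape
        u = self.units
        self.params["Wx"] = _glorot_uniform(rng, (c, 4 * u), c, 4 * u)
        self.params["Wh"] = _glorot_uniform(rng, (u, 4 * u), u, 4 * u)
        b = np.zeros(4 * u, dtype=DTYPE)
        b[u : 2 * u] = 1.0  # forget-gate bias
        self.params["b"] = b
        self.built = True
        return (t, u) if self.return_sequences else (u,)

    def forward(self, x, training=False):
        n, t, c = x.shape
        u = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((n, u), dtype=DTYPE)
        cst = np.zeros((n, u), dtype=DTYPE)
        self._x = x
        self._cache = []
        hs = np.empty((n, t, u), dtype=DTYPE)
        for step in range(t):
            z = x[:, step] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_prev = cst
            cst = f * c_prev + i * g
            tc = np.tanh(cst)
            h_prev = h
            h = o * tc
            hs[:, step] = h
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, dy):
        x = self._x
        n, t, c = x.shape
        u = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, u), dtype=DTYPE)
        dc_next = np.zeros((n, u), dtype=DTYPE)
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[step]
            dh = dh_next + (dy[:, step] if self.return_sequences else 0)
            if not self.return_sequences and step == t - 1:
                dh = dh + dy
            dc = dc_next + dh * o * (1.0 - tc**2)
            do = dh * tc
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x[:, step].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        self.grads["Wx"] = dWx
        self.grads["Wh"] = dWh
        self.grads["b"] = db
        return dx
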