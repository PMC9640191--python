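"""Layers with explicit forward/backward passes.

Shapes exclude the batch axis: sequence layers map (T, C) -> (T, F); dense
layers map (F,) -> (U) (and apply over the last axis of higher-rank input).
Each layer owns its parameters and, after a backward pass, their gradients.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from surroneuron.nn import activations as act
from surroneuron.nn.initializers import init_weights, default_initializer


class Layer:
    trainable = True

    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}
        self.built = False

    def build(self, input_shape: Tuple[int, ...], rng: np.random.Generator) -> Tuple[int, ...]:
        self.built = True
        return input_shape

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def regularization_loss(self) -> float:
        return 0.0

    def add_regularization_grads(self) -> None:
        pass

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def get_config(self) -> dict:
        return {}


class Dense(Layer):
    def __init__(self, units: int, activation: Optional[str] = None, initializer: Optional[str] = None):
        super().__init__()
        self.units = units
        self.activation = activation
        self.initializer = initializer or default_initializer(activation)

    def build(self, input_shape, rng):
        fan_in = input_shape[-1]
        self.params["W"] = init_weights(self.initializer, (fan_in, self.units), fan_in, self.units, rng)
        self.params["b"] = np.zeros(self.units)
        self.built = True
        return tuple(input_shape[:-1]) + (self.units,)

    def forward(self, x, training=False):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        self._z = z
        self._out = act.forward(self.activation, z)
        return self._out

    def backward(self, dy):
        dz = act.backward(self.activation, self._z, self._out, dy)
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dz2 = dz.reshape(-1, self.units)
        self.grads["W"] = x2.T @ dz2
        self.grads["b"] = dz2.sum(axis=0)
        return dz @ self.params["W"].T

    def get_config(self):
        return {"units": self.units, "activation": self.activation, "initializer": self.initializer}


class Conv1D(Layer):
    """Causal (left-padded), optionally dilated 1-D convolution over time."""

    def __init__(
        self,
        filters: int,
        kernel_size: int,
        dilation: int = 1,
        activation: Optional[str] = None,
        initializer: Optional[str] = None,
        l1: float = 0.0,
    ):
        super().__init__()
        self.filters = filters
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.activation = activation
        self.initializer = initializer or default_initializer(activation)
        self.l1 = l1

    def build(self, input_shape, rng):
        T, C = input_shape
        fan_in = C * self.kernel_size
        fan_out = self.filters * self.kernel_size
        self.params["W"] = init_weights(
            self.initializer, (self.kernel_size, C, self.filters), fan_in, fan_out, rng
        )
        self.params["b"] = np.zeros(self.filters)
        self.built = True
        return (T, self.filters)

    def forward(self, x, training=False):
        B, T, C = x.shape
        pad = (self.kernel_size - 1) * self.dilation
        xp = np.pad(x, ((0, 0), (pad, 0), (0, 0)))
        self._xp = xp
        self._T = T
        z = np.zeros((B, T, self.filters))
        for k in range(self.kernel_size):
            z += xp[:, k * self.dilation : k * self.dilation + T, :] @ self.params["W"][k]
        z += self.params["b"]
        self._z = z
        self._out = act.forward(self.activation, z)
        return self._out

    def backward(self, dy):
        dz = act.backward(self.activation, self._z, self._out, dy)
        T = self._T
        W = self.params["W"]
        dW = np.zeros_like(W)
        dxp = np.zeros_like(self._xp)
        for k in range(self.kernel_size):
            sl = slice(k * self.dilation, k * self.dilation + T)
            xs = self._xp[:, sl, :]
            dW[k] = np.einsum("btc,btf->cf", xs, dz)
            dxp[:, sl, :] += dz @ W[k].T
        self.grads["W"] = dW
        self.grads["b"] = dz.sum(axis=(0, 1))
        pad = (self.kernel_size - 1) * self.dilation
        return dxp[:, pad:, :] if pad else dxp

    def regularization_loss(self):
        return self.l1 * float(np.abs(self.params["W"]).sum()) if self.l1 else 0.0

    def add_regularization_grads(self):
        if self.l1:
            self.grads["W"] = self.grads["W"] + self.l1 * np.sign(self.params["W"])

    def get_config(self):
        return {
            "filters": self.filters,
            "kernel_size": self.kernel_size,
            "dilation": self.dilation,
            "activation": self.activation,
            "initializer": self.initializer,
            "l1": self.l1,
        }


class LSTM(Layer):
    """Single LSTM layer (gate order i, f, g, o) with full BPTT."""

    def __init__(self, units: int, return_sequences: bool = False, initializer: str = "glorot_uniform"):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        self.initializer = initializer

    def build(self, input_shape, rng):
        T, F = input_shape
        U = self.units
        self.params["Wx"] = init_weights(self.initializer, (F, 4 * U), F, 4 * U, rng)
        # recurrent kernel: orthogonal-ish via the same uniform rule
        self.params["Wh"] = init_weights(self.initializer, (U, 4 * U), U, 4 * U, rng)
        self.params["b"] = np.zeros(4 * U)
        self.built = True
        return (T, U) if self.return_sequences else (U,)

    def forward(self, x, training=False):
        B, T, F = x.shape
        U = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, U))
        for t in range(T):
            z = x[:, t, :] @ Wx + h @ Wh + b
            i = 1.0 / (1.0 + np.exp(-z[:, :U]))
            f = 1.0 / (1.0 + np.exp(-z[:, U : 2 * U]))
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * U :]))
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, dy):
        x = self._x
        B, T, F = x.shape
        U = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * U)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, U))
        dc_next = np.zeros((B, U))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dy[:, t, :]
            elif t == T - 1:
                dh += dy
            dc = dc_next + dh * o * (1.0 - tc * tc)
            do = dh * tc
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        self.grads["Wx"] = dWx
        self.grads["Wh"] = dWh
        self.grads["b"] = db
        return dx

    def get_config(self):
        return {
            "units": self.units,
            "return_sequences": self.return_sequences,
            "initializer": self.initializer,
        }


class Flatten(Layer):
    def build(self, input_shape, rng):
        self._shape = tuple(input_shape)
        self.built = True
        return (int(np.prod(input_shape)),)

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class RepeatVector(Layer):
    def __init__(self, n: int = 1):
        super().__init__()
        self.n = n

    def build(self, input_shape, rng):
        self.built = True
        return (self.n,) + tuple(input_shape)

    def forward(self, x, training=False):
        return np.repeat(x[:, None, :], self.n, axis=1)

    def backward(self, dy):
        return dy.sum(axis=1)

    def get_config(self):
        return {"n": self.n}


class TakeLast(Layer):
    """Keep only the last timestep of a sequence (causal prediction head)."""

    def build(self, input_shape, rng):
        self.built = True
        return (input_shape[-1],)

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x[:, -1, :]

    def backward(self, dy):
        dx = np.zeros(self._in_shape)
        dx[:, -1, :] = dy
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, seed: int = 0):
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def build(self, input_shape, rng):
        self.rng = np.random.default_rng(rng.integers(2**31))
        self.built = True
        return input_shape

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def get_config(self):
        return {"rate": self.rate}


class NmdaGate(Layer):
    """Non-trainable input gate: rescales the NMDA conductance channel by a
    Boltzmann function of the instantaneous (normalized) voltage channel.

    Operates on the raw input window (B, T, C); parameters live in the
    normalized layer space (defaults x0 = 1.44, dx = 0.12).
    """

    trainable = False

    def __init__(
        self,
        nmda_channel: int,
        v_channel: int = 0,
        a1: float = 1.0,
        a2: float = -1.0,
        x0: float = 1.44,
        dx: float = 0.12,
    ):
        super().__init__()
        self.nmda_channel = nmda_channel
        self.v_channel = v_channel
        self.a1, self.a2, self.x0, self.dx = a1, a2, x0, dx

    def build(self, input_shape, rng):
        if self.nmda_channel >= input_shape[-1]:
            raise ValueError("input has no NMDA channel at the configured index")
        self.built = True
        return input_shape

    def gate(self, v):
        arg = np.clip((self.x0 - v) / self.dx, -60.0, 60.0)
        return self.a2 + (self.a1 - self.a2) / (1.0 + np.exp(arg))

    def forward(self, x, training=False):
        v = x[..., self.v_channel]
        g = self.gate(v)
        self._v = v
        self._g = g
        self._n_in = x[..., self.nmda_channel].copy()
        out = x.copy()
        out[..., self.nmda_channel] = self._n_in * g
        return out

    def backward(self, dy):
        dx = dy.copy()
        dn = dy[..., self.nmda_channel]
        dx[..., self.nmda_channel] = dn * self._g
        # gate'(v) = (a1-a2) * s * (1-s) / dx with s the logistic factor
        s = (self._g - self.a2) / (self.a1 - self.a2)
        dgdv = (self.a1 - self.a2) * s * (1.0 - s) / self.dx
        dx[..., self.v_channel] += dn * self._n_in * dgdv
        return dx

    def get_config(self):
        return {
            "nmda_channel": self.nmda_channel,
            "v_channel": self.v_channel,
            "a1": self.a1,
            "a2": self.a2,
            "x0": self.x0,
            "dx": self.dx,
        }


class OutputBias(Layer):
    """Single trainable additive bias on the output (post-hoc correction of
    the skew that non-normally distributed voltage targets induce)."""

    def build(self, input_shape, rng):
        self.params["b"] = np.zeros(input_shape[-1])
        self.built = True
        return input_shape

    def forward(self, x, training=False):
        return x + self.params["b"]

    def backward(self, dy):
        self.grads["b"] = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy
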