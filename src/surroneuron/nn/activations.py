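"""Elementwise activations and their derivatives (as functions of the
pre-activation, with the forward output available for reuse)."""

from __future__ import annotations

import numpy as np

SELU_SCALE = 1.0507009873554805
SELU_ALPHA = 1.6732632423543772


def forward(name, z):
    if name is None or name == "linear":
        return z
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "tanh":
        return np.tanh(z)
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "selu":
        return SELU_SCALE * np.where(z > 0, z, SELU_ALPHA * np.expm1(z))
    raise ValueError(f"unknown activation: {name}")


def backward(name, z, out, dy):
    """dL/dz given dL/dy, using pre-activation z and output y."""
    if name is None or name == "linear":
        return dy
    if name == "sigmoid":
        return dy * out * (1.0 - out)
    if name == "tanh":
        return dy * (1.0 - out * out)
    if name == "relu":
        return dy * (z > 0)
    if name == "selu":
        return dy * SELU_SCALE * np.where(z > 0, 1.0, SELU_ALPHA * np.exp(z))
    raise ValueError(f"unknown activation: {name}")
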