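"""Weight initializers (uniform variance-scaling family)."""

from __future__ import annotations

import numpy as np


def init_weights(name: str, shape, fan_in: int, fan_out: int, rng: np.random.Generator):
    if name == "he_uniform":
        limit = np.sqrt(6.0 / fan_in)
    elif name == "glorot_uniform":
        limit = np.sqrt(6.0 / (fan_in + fan_out))
    elif name == "lecun_uniform":
        limit = np.sqrt(3.0 / fan_in)
    else:
        raise ValueError(f"unknown initializer: {name}")
    return rng.uniform(-limit, limit, size=shape)


def default_initializer(activation) -> str:
    """Pair each activation with its conventional variance-scaling rule."""
    if activation == "relu":
        return "he_uniform"
    if activation == "selu":
        return "lecun_uniform"
    return "glorot_uniform"
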