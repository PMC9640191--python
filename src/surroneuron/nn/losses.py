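"""Losses with gradients (mean over all elements)."""

from __future__ import annotations

import numpy as np


def mse(pred, target):
    d = pred - target
    return float(np.mean(d * d)), 2.0 * d / d.size


def mae(pred, target):
    d = pred - target
    return float(np.mean(np.abs(d))), np.sign(d) / d.size


def get_loss(name: str):
    if name == "mse":
        return mse
    if name == "mae":
        return mae
    raise ValueError(f"unknown loss: {name}")
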