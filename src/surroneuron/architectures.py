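"""Builders for the five forecasting architectures and the multicompartment
CNN-LSTM.

All models consume a 64-sample history window of C channels and emit the next
sample of the predicted channels.  The five point-neuron stacks:

``linear``     flatten -> 64-unit affine map -> affine head
``nonlinear``  the same with a sigmoid on the hidden map
``deep``       64-unit map + nine tanh layers (128..1024..64) with 0.15 dropout
``convnet``    12 causal dilated convolutions (128 filters, kernel 2, tanh,
               dilation 2^n), last-timestep affine head
``cnn_lstm``   convolutions 128/100/50 (kernels 1/5/1, relu/relu/tanh),
               flatten + repeat, two stacked 128-unit LSTM layers, four
               100-unit SELU layers with 0.15 dropout, affine head

With the 5-channel input (v, exc, inh, I_Na, I_K) the free-parameter counts
are 2.07e4 / 2.07e4 / 2.47e6 / 3.64e5 / 1.95e6 respectively.

The multicompartment variant (``build_multi``) takes 201 channels (somatic
voltage + 200 synapse rows): convolutions 512/256/128 with an L1 penalty on
the first layer, three 128-unit LSTM layers, dense stack 128/100/100/100/100
and a trainable output-bias correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from surroneuron.data import NormalizationParams
from surroneuron.nn import (
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    LSTM,
    NmdaGate,
    OutputBias,
    RepeatVector,
    Sequential,
    TakeLast,
)

ARCHITECTURES = ("linear", "nonlinear", "deep", "convnet", "cnn_lstm", "cnn_lstm_multi")

DEEP_STACK = (128, 256, 512, 1024, 1024, 512, 256, 128, 64)


@dataclass
class ArchitectureSpec:
    name: str
    input_channels: int
    output_width: int
    window: int = 64
    extras: dict = field(default_factory=dict)


@dataclass
class SurrogateModel:
    """An architecture instance plus its normalization contract."""

    net: Sequential
    spec: ArchitectureSpec
    norm: Optional[NormalizationParams] = None
    channel_names: Optional[List[str]] = None

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def predict(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        return self.net.predict(x, batch_size=batch_size)

    def save(self, path) -> None:
        import json
        from pathlib import Path

        self.net.save(path)
        meta = {
            "name": self.spec.name,
            "input_channels": self.spec.input_channels,
            "output_width": self.spec.output_width,
            "window": self.spec.window,
            "extras": self.spec.extras,
            "channel_names": self.channel_names,
            "norm": self.norm.to_dict() if self.norm else None,
        }
        (Path(path) / "surrogate.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        import json
        from pathlib import Path

        net = Sequential.load(path)
        meta = json.loads((Path(path) / "surrogate.json").read_text())
        return cls(
            net=net,
            spec=ArchitectureSpec(
                meta["name"],
                meta["input_channels"],
                meta["output_width"],
                meta["window"],
                meta.get("extras", {}),
            ),
            norm=NormalizationParams.from_dict(meta["norm"]) if meta["norm"] else None,
            channel_names=meta.get("channel_names"),
        )


def _head(output_width: int) -> Dense:
    return Dense(output_width, activation=None)


def build(
    name: str,
    input_channels: int = 5,
    output_width: int = 1,
    window: int = 64,
    seed: int = 0,
    channel_names: Optional[List[str]] = None,
    norm: Optional[NormalizationParams] = None,
) -> SurrogateModel:
    """Instantiate one of the five point-neuron architectures."""
    shape = (window, input_channels)
    if name == "linear":
        layers = [Flatten(), Dense(64, activation=None), _head(output_width)]
    elif name == "nonlinear":
        layers = [Flatten(), Dense(64, activation="sigmoid"), _head(output_width)]
    elif name == "deep":
        layers = [Flatten(), Dense(64, activation=None)]
        for units in DEEP_STACK:
            layers += [Dense(units, activation="tanh"), Dropout(0.15)]
        layers.append(_head(output_width))
    elif name == "convnet":
        layers = [
            Conv1D(128, kernel_size=2, dilation=2**n, activation="tanh") for n in range(12)
        ]
        layers += [TakeLast(), _head(output_width)]
    elif name == "cnn_lstm":
        layers = [
            Conv1D(128, kernel_size=1, activation="relu", initializer="he_uniform"),
            Conv1D(100, kernel_size=5, activation="relu", initializer="he_uniform"),
            Conv1D(50, kernel_size=1, activation="tanh", initializer="glorot_uniform"),
            Flatten(),
            RepeatVector(1),
            LSTM(128, return_sequences=True),
            LSTM(128, return_sequences=False),
        ]
        for _ in range(4):
            layers += [Dense(100, activation="selu", initializer="lecun_uniform"), Dropout(0.15)]
        layers.append(_head(output_width))
    else:
        raise ValueError(f"unknown architecture: {name}")
    net = Sequential(layers, shape, seed=seed)
    return SurrogateModel(
        net=net,
        spec=ArchitectureSpec(name, input_channels, output_width, window),
        norm=norm,
        channel_names=channel_names,
    )


def build_multi(
    synapse_count: int = 200,
    output_width: int = 1,
    window: int = 64,
    seed: int = 0,
    l1: float = 1e-5,
    norm: Optional[NormalizationParams] = None,
) -> SurrogateModel:
    """The multicompartment CNN-LSTM over (window x (1 + synapse_count))."""
    if synapse_count <= 0:
        raise ValueError("synapse_count must be positive")
    channels = 1 + synapse_count
    layers = [
        Conv1D(512, kernel_size=1, activation="relu", initializer="he_uniform", l1=l1),
        Conv1D(256, kernel_size=5, activation="relu", initializer="he_uniform"),
        Conv1D(128, kernel_size=1, activation="tanh", initializer="glorot_uniform"),
        Flatten(),
        RepeatVector(1),
        LSTM(128, return_sequences=True),
        LSTM(128, return_sequences=True),
        LSTM(128, return_sequences=False),
        Dense(128, activation="relu", initializer="he_uniform"),
        Dropout(0.15),
    ]
    for _ in range(4):
        layers += [Dense(100, activation="selu", initializer="lecun_uniform"), Dropout(0.15)]
    layers += [_head(output_width), OutputBias()]
    net = Sequential(layers, (window, channels), seed=seed)
    names = ["v"] + [f"syn{i}" for i in range(synapse_count)]
    return SurrogateModel(
        net=net,
        spec=ArchitectureSpec(
            "cnn_lstm_multi", channels, output_width, window, extras={"l1": l1}
        ),
        norm=norm,
        channel_names=names,
    )


def attach_nmda_head(
    model: SurrogateModel,
    boltzmann: Tuple[float, float, float, float] = (1.0, -1.0, 1.44, 0.12),
    nmda_channel: Optional[int] = None,
) -> SurrogateModel:
    """Insert the fixed (non-trainable) NMDA voltage-gate layer at the input.

    The layer rescales the NMDA conductance channel by the Boltzmann gate of
    the instantaneous voltage channel, in normalized layer space.
    """
    if nmda_channel is None:
        if not model.channel_names or "nmda" not in model.channel_names:
            raise ValueError("model has no NMDA channel (set channel_names or nmda_channel)")
        nmda_channel = model.channel_names.index("nmda")
    a1, a2, x0, dx = boltzmann
    gate = NmdaGate(nmda_channel=nmda_channel, a1=a1, a2=a2, x0=x0, dx=dx)
    old_weights = model.net.weights_flat()
    net = Sequential([gate] + model.net.layers, model.net.input_shape, seed=model.net.seed)
    # re-building re-initialized the existing layers; restore their weights
    net.set_weights({f"{int(k.split('.')[0]) + 1}.{k.split('.', 1)[1]}": v for k, v in old_weights.items()})
    spec = ArchitectureSpec(
        model.spec.name,
        model.spec.input_channels,
        model.spec.output_width,
        model.spec.window,
        {**model.spec.extras, "nmda_gate": list(boltzmann)},
    )
    return SurrogateModel(net=net, spec=spec, norm=model.norm, channel_names=model.channel_names)


def extract_first_layer_filters(model: SurrogateModel):
    """First-convolution weights and per-synapse selectivity.

    Returns (weights, selectivity): weights shaped (filters, channels,
    kernel); selectivity is max |weight| over the kernel taps for each
    non-voltage input channel, shaped (filters, synapse channels).
    """
    conv = next((l for l in model.net.layers if isinstance(l, Conv1D)), None)
    if conv is None:
        raise ValueError("architecture has no convolutional front end")
    W = conv.params["W"]  # (K, C, F)
    weights = np.transpose(W, (2, 1, 0))  # (F, C, K)
    syn_cols = [
        i
        for i, name in enumerate(model.channel_names or [])
        if name not in ("v",) and not name.startswith("i_")
    ]
    if not syn_cols:
        syn_cols = list(range(1, weights.shape[1]))
    selectivity = np.abs(weights[:, syn_cols, :]).max(axis=2)
    return weights, selectivity
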