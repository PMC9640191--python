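"""A minimal sequential model container with save/load."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, List, Optional, Tuple

import numpy as np

from surroneuron.nn import layers as L


LAYER_TYPES = {
    cls.__name__: cls
    for cls in (
        L.Dense,
        L.Conv1D,
        L.LSTM,
        L.Flatten,
        L.RepeatVector,
        L.TakeLast,
        L.Dropout,
        L.NmdaGate,
        L.OutputBias,
    )
}


class Sequential:
    def __init__(self, layers: List[L.Layer], input_shape: Tuple[int, ...], seed: int = 0):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.seed = seed
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in self.layers:
            layer.frozen = getattr(layer, "frozen", False)
            shape = layer.build(shape, rng)
        self.output_shape = shape

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
            layer.add_regularization_grads()
        return dy

    def regularization_loss(self) -> float:
        return sum(layer.regularization_loss() for layer in self.layers)

    def predict(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        outs = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs) if len(outs) > 1 else outs[0]

    def trainable_params(self):
        """Yield (key, param array, grad array) for unfrozen trainable layers."""
        for i, layer in enumerate(self.layers):
            if not layer.trainable or layer.frozen:
                continue
            for name, p in layer.params.items():
                yield f"{i}.{name}", p, layer.grads.get(name)

    def freeze(self, predicate: Callable[[int, L.Layer], bool]) -> int:
        """Freeze layers selected by predicate(index, layer); returns the
        number of trainable layers left unfrozen."""
        n_open = 0
        for i, layer in enumerate(self.layers):
            layer.frozen = bool(predicate(i, layer))
            if layer.trainable and not layer.frozen and layer.params:
                n_open += 1
        if n_open == 0:
            raise ValueError("freeze predicate left no trainable layers")
        return n_open

    def weights_flat(self) -> dict:
        return {
            f"{i}.{name}": p
            for i, layer in enumerate(self.layers)
            for name, p in layer.params.items()
        }

    def set_weights(self, flat: dict) -> None:
        for key, value in flat.items():
            idx, name = key.split(".", 1)
            self.layers[int(idx)].params[name][:] = value

    # -- persistence: JSON descriptor + npz weight bundle --------------------

    def describe(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "seed": self.seed,
            "layers": [
                {"type": type(layer).__name__, "config": layer.get_config()}
                for layer in self.layers
            ],
        }

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "architecture.json").write_text(json.dumps(self.describe(), indent=1))
        np.savez(path / "weights.npz", **self.weights_flat())

    @classmethod
    def from_description(cls, desc: dict) -> "Sequential":
        layers = [LAYER_TYPES[d["type"]](**d["config"]) for d in desc["layers"]]
        return cls(layers, tuple(desc["input_shape"]), seed=desc.get("seed", 0))

    @classmethod
    def load(cls, path) -> "Sequential":
        path = Path(path)
        desc = json.loads((path / "architecture.json").read_text())
        model = cls.from_description(desc)
        with np.load(path / "weights.npz") as npz:
            model.set_weights({k: npz[k] for k in npz.files})
        return model
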