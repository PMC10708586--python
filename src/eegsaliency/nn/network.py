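"""Sequential network container with seeded initialisation and checkpoints."""

from __future__ import annotations

import json

import numpy as np

from .layers import Layer


class Sequential:
    """An ordered layer chain operating on a fixed input shape.

    Parameters are initialised from ``seed`` at build time so that two
    networks built with the same layers, input shape and seed are
    bit-identical.  Data layout is channel-first: 3-D activations are
    (channels, height, width) without the batch axis.
    """

    def __init__(self, layers: list[Layer], input_shape, seed: int = 42, dtype=np.float64):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.seed = int(seed)
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(self.seed)
        self.out_shapes = []
        shape = self.input_shape
        for layer in layers:
            shape = layer.init(rng, shape, self.dtype)
            self.out_shapes.append(tuple(shape))
        self.output_shape = tuple(shape)

    # -- execution ---------------------------------------------------------
    def forward(self, x, training: bool = False):
        x = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            layer.training = training
            x = layer.forward(x)
        return x

    def __call__(self, x, training: bool = False):
        return self.forward(x, training=training)

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def forward_upto(self, x, n_layers: int, training: bool = False):
        """Forward through the first ``n_layers`` layers only."""
        x = np.asarray(x, dtype=self.dtype)
        for layer in self.layers[:n_layers]:
            layer.training = training
            x = layer.forward(x)
        return x

    # -- parameters --------------------------------------------------------
    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield f"{i}.{name}", layer, name, p

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def count_parameters(self):
        """Per-layer table: layer index, description, output shape, weights."""
        rows = []
        for i, (layer, shape) in enumerate(zip(self.layers, self.out_shapes)):
            rows.append(
                {
                    "layer": i + 1,
                    "name": layer.describe(),
                    "output_shape": shape,
                    "n_params": layer.n_params,
                }
            )
        return rows

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {key: p.copy() for key, _, _, p in self.parameters()}
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "running_mean"):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state):
        for key, layer, name, p in self.parameters():
            src = np.asarray(state[key], dtype=self.dtype)
            if src.shape != p.shape:
                raise ValueError(
                    f"shape mismatch for {key}: expected {p.shape}, got {src.shape}"
                )
            layer.params[name] = src.copy()
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "running_mean"):
                layer.running_mean = np.asarray(
                    state[f"{i}.running_mean"], dtype=self.dtype
                ).copy()
                layer.running_var = np.asarray(
                    state[f"{i}.running_var"], dtype=self.dtype
                ).copy()

    def save(self, path, meta: dict | None = None):
        arrays = self.state_dict()
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta or {}).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)
        return path


def load_meta(path) -> dict:
    with np.load(path) as data:
        return json.loads(bytes(data["__meta__"]).decode())


def load_state(path) -> dict:
    with np.load(path) as data:
        return {k: data[k] for k in data.files if k != "__meta__"}
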