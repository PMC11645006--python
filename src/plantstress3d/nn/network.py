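"""Sequential container with spec-based construction and npz checkpoints.

A network is described by a *spec*: a list of ``(kind, *args)`` tuples, e.g.
``[("conv", 3, 8), ("bn", 8), ("relu",), ("pool",), ("flatten",),
("dense", 256, 2)]``. The spec is serialised next to the weights so a
checkpoint is self-describing.
"""

from __future__ import annotations

import json

import numpy as np

from .layers import BatchNorm, Conv2D, Dense, Flatten, MaxPool2D, ReLU

_LAYER_FACTORIES = {
    "conv": Conv2D,
    "bn": BatchNorm,
    "relu": ReLU,
    "pool": MaxPool2D,
    "flatten": Flatten,
    "dense": Dense,
}


class Sequential:
    def __init__(self, spec, rng=None):
        self.spec = [tuple(s) for s in spec]
        self.layers = [_LAYER_FACTORIES[s[0]](*s[1:]) for s in self.spec]
        if rng is not None:
            self.init(rng)

    def init(self, rng):
        for layer in self.layers:
            layer.init(rng)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    # -- introspection ---------------------------------------------------

    def count(self, kind):
        """Number of layers of a given spec kind (e.g. 'conv')."""
        return sum(1 for s in self.spec if s[0] == kind)

    def dense_sizes(self):
        """(in, out) feature sizes of all dense layers, in order."""
        return [(s[1], s[2]) for s in self.spec if s[0] == "dense"]

    # -- persistence -----------------------------------------------------

    def state_arrays(self):
        arrays = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                arrays[f"l{i}p{j}"] = p.value
            if isinstance(layer, BatchNorm):
                arrays[f"l{i}rm"] = layer.running_mean
                arrays[f"l{i}rv"] = layer.running_var
        return arrays

    def load_state_arrays(self, arrays):
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                p.value = np.asarray(arrays[f"l{i}p{j}"], dtype=float)
                p.grad = np.zeros_like(p.value)
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(arrays[f"l{i}rm"], dtype=float)
                layer.running_var = np.asarray(arrays[f"l{i}rv"], dtype=float)

    def save(self, path, metadata=None):
        arrays = self.state_arrays()
        arrays["__spec__"] = np.frombuffer(
            json.dumps(self.spec).encode(), dtype=np.uint8
        )
        arrays["__meta__"] = np.frombuffer(
            json.dumps(metadata or {}).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path) as data:
            spec = json.loads(bytes(data["__spec__"].tobytes()).decode())
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            net = cls(spec)
            net.load_state_arrays(data)
        return net, meta
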