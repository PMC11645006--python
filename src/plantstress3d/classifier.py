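"""Plant stress classification from leaf-centroid features.

The feature vector has a fixed length of 15. In ``heights`` mode it holds
the centroid Z (camera distance, meters) of up to 15 leaves; in
``full_centroids`` mode the (X, Y, Z) centroids of up to 5 leaves. Leaves
are ordered by pixel count descending (ties broken by centroid X then Y
ascending); missing slots carry ``pad_value``.

The classifier is a fully connected network with layer sizes
15-128-64-32-64-128-2, ReLU hidden activations and two sigmoid output
units (stress / no-stress); the decision thresholds the stress score at
0.5, so 1 means stressed and 0 means without stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Sequential, build_mlp, fit, sigmoid, sigmoid_bce_loss

__all__ = [
    "FEATURE_LENGTH",
    "LAYER_SIZES",
    "FeatureVector",
    "StressModel",
    "build_feature_vector",
    "classify_stress",
    "train_stress_dnn",
    "write_predictions_csv",
]

FEATURE_LENGTH = 15
LAYER_SIZES = (15, 128, 64, 32, 64, 128, 2)


@dataclass
class FeatureVector:
    values: np.ndarray  # length 15
    mode: str = "heights"
    pad_value: float = 0.0
    n_leaves: int = 0  # leaves that contributed before padding/truncation

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if len(self.values) != FEATURE_LENGTH:
            raise ValueError(f"feature vector must have length {FEATURE_LENGTH}")


def order_leaves(leaves):
    """Sort leaves by pixel count descending, ties by centroid X then Y."""
    return sorted(
        leaves, key=lambda lf: (-lf.w, lf.centroid[0], lf.centroid[1])
    )


def build_feature_vector(leaves, mode="heights", pad_value=0.0) -> FeatureVector:
    """Fixed-length feature vector from reconstructed leaves (may be empty)."""
    if mode not in ("heights", "full_centroids"):
        raise ValueError(f"unknown feature mode {mode!r}")
    ordered = order_leaves(leaves)
    if mode == "heights":
        values = [leaf.centroid[2] for leaf in ordered[:FEATURE_LENGTH]]
    else:
        values = []
        for leaf in ordered[: FEATURE_LENGTH // 3]:
            values.extend(leaf.centroid)
    values = list(values)[:FEATURE_LENGTH]
    n_used = len(values) if mode == "heights" else min(len(ordered), 5)
    values += [pad_value] * (FEATURE_LENGTH - len(values))
    return FeatureVector(
        values=np.array(values), mode=mode, pad_value=pad_value, n_leaves=n_used
    )


@dataclass
class StressModel:
    net: Sequential
    meta: dict = field(default_factory=dict)
    history: list = field(default_factory=list)

    def layer_sizes(self):
        """(in, hidden..., out) sizes recovered from the dense layers."""
        dense = self.net.dense_sizes()
        return tuple([dense[0][0]] + [b for _, b in dense])

    def predict_scores(self, features):
        """Sigmoid output of the stress unit for (n, 15) feature rows."""
        x = np.asarray(features, dtype=float)
        offset = np.asarray(self.meta.get("input_offset", 0.0))
        scale = np.asarray(self.meta.get("input_scale", 1.0))
        logits = self.net.forward((x - offset) / scale)
        return sigmoid(logits[:, 1])

    def save(self, path):
        self.net.save(path, metadata=self.meta)

    @classmethod
    def load(cls, path):
        net, meta = Sequential.load(path)
        return cls(net=net, meta=meta)


def train_stress_dnn(
    features,
    labels,
    seed,
    *,
    epochs=60,
    batch_size=32,
    lr=1e-3,
    betas=(0.9, 0.999),
):
    """Seeded training of the fixed 15-128-64-32-64-128-2 architecture.

    Both output units are trained one-hot with binary cross-entropy on
    their sigmoid activations. Inputs are standardised per feature slot
    (leaf heights vary by centimeters around a large offset, which
    conditions the optimisation badly on the raw scale); the affine is
    stored with the model and applied at prediction time.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2 or features.shape[1] != FEATURE_LENGTH:
        raise ValueError(f"features must be (n, {FEATURE_LENGTH})")
    present = set(np.unique(labels))
    if present != {0, 1}:
        missing = {0, 1} - present
        raise ValueError(f"training set is missing class(es) {sorted(missing)}")
    onehot = np.zeros((len(labels), 2))
    onehot[np.arange(len(labels)), labels] = 1.0
    offset = features.mean(axis=0)
    scale = np.maximum(features.std(axis=0), 1e-8)
    rng = np.random.default_rng(seed)
    net = build_mlp(LAYER_SIZES, rng=rng)
    history = fit(
        net,
        (features - offset) / scale,
        onehot,
        sigmoid_bce_loss,
        epochs=epochs,
        batch_size=batch_size,
        lr=lr,
        betas=betas,
        rng=rng,
        accuracy_fn=lambda logits, y: (
            (logits[:, 1] > logits[:, 0]) == y[:, 1].astype(bool)
        ).mean(),
    )
    meta = {
        "task": "stress",
        "seed": int(seed),
        "epochs": epochs,
        "lr": lr,
        "batch_size": batch_size,
        "layer_sizes": list(LAYER_SIZES),
        "input_offset": offset.tolist(),
        "input_scale": scale.tolist(),
    }
    return StressModel(net=net, meta=meta, history=history)


def classify_stress(model: StressModel, feature):
    """(label, score): score is the stress unit's sigmoid output in (0, 1);
    label = 1 (stressed) when the score exceeds 0.5, else 0."""
    values = feature.values if isinstance(feature, FeatureVector) else feature
    values = np.asarray(values, dtype=float).reshape(-1)
    if len(values) != FEATURE_LENGTH:
        raise ValueError(f"feature vector must have length {FEATURE_LENGTH}")
    score = float(model.predict_scores(values[None, :])[0])
    return int(score > 0.5), score


def write_predictions_csv(path, records):
    """records: iterable of (record_id, score, label)."""
    with open(path, "w") as fh:
        fh.write("record_id,score,label\n")
        for rec_id, score, label in records:
            fh.write(f"{rec_id},{score:.6f},{label}\n")
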