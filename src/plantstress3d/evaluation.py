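"""Quantitative evaluation machinery.

Confusion-count metrics (recall, precision, F-score, accuracy, specificity,
Jaccard index), trapezoidal ROC AUC, the Polygon Area Metric (PAM),
seeded k-fold cross-validation, method-comparison deltas, and the
moisture-ratio utility for leaf-drying curves.

Metrics with a zero denominator are returned as ``None`` and listed in the
bundle's ``undefined`` set — never silently coerced to 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "ConfusionCounts",
    "HEXAGON_AREA",
    "MetricsBundle",
    "PAM_VERTEX_ORDER",
    "auc",
    "basic_metrics",
    "compare_methods",
    "f_score_from_precision_recall",
    "kfold_cv",
    "kfold_indices",
    "mean_bundle",
    "metrics_to_csv",
    "metrics_to_json",
    "moisture_ratio",
    "pam",
    "plot_pam",
]

#: Exact area of a regular hexagon with unit sides (3 * sqrt(3) / 2);
#: the truncated value 2.59807 is used only in reporting.
HEXAGON_AREA = 3.0 * math.sqrt(3.0) / 2.0

PAM_VERTEX_ORDER = ("recall", "specificity", "jaccard", "accuracy", "f_score", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self):
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, predicted, truth):
        predicted = np.asarray(predicted).astype(bool).ravel()
        truth = np.asarray(truth).astype(bool).ravel()
        if predicted.shape != truth.shape:
            raise ValueError("prediction and truth must have the same length")
        return cls(
            tp=int(np.sum(predicted & truth)),
            tn=int(np.sum(~predicted & ~truth)),
            fp=int(np.sum(predicted & ~truth)),
            fn=int(np.sum(~predicted & truth)),
        )


@dataclass
class MetricsBundle:
    recall: float | None = None
    precision: float | None = None
    f_score: float | None = None
    accuracy: float | None = None
    specificity: float | None = None
    jaccard: float | None = None
    auc: float | None = None
    pa: float | None = None
    pam: float | None = None
    undefined: set = field(default_factory=set)

    def as_dict(self):
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "undefined"
        }


def _ratio(num, den):
    return None if den == 0 else num / den


def basic_metrics(counts: ConfusionCounts) -> MetricsBundle:
    """Recall, precision, F-score, accuracy, specificity and Jaccard index."""
    b = MetricsBundle(
        recall=_ratio(counts.tp, counts.tp + counts.fn),
        precision=_ratio(counts.tp, counts.tp + counts.fp),
        f_score=_ratio(counts.tp, counts.tp + 0.5 * (counts.fp + counts.fn)),
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        jaccard=_ratio(counts.tp, counts.tp + counts.fp + counts.fn),
    )
    b.undefined = {k for k, v in b.as_dict().items() if v is None} - {"auc", "pa", "pam"}
    return b


def f_score_from_precision_recall(precision, recall):
    """Harmonic mean 2 * p * r / (p + r)."""
    if precision + recall == 0:
        raise ValueError("precision + recall must be > 0")
    return 2.0 * precision * recall / (precision + recall)


def auc(scores, labels):
    """Trapezoidal area under the ROC curve obtained by sweeping the score
    threshold. Ties in scores are handled by grouping (equivalent to the
    Mann-Whitney U statistic with the tie correction)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(bool).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes to be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group tied scores so the ROC steps diagonally through ties
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.concatenate([distinct, [len(s) - 1]])
    tps = np.concatenate([[0], np.cumsum(y)[cut]])
    fps = np.concatenate([[0], np.cumsum(~y)[cut]])
    return float(np.trapezoid(tps / n_pos, fps / n_neg))


def pam(values, vertex_order=PAM_VERTEX_ORDER):
    """Polygon Area Metric.

    ``values`` is a MetricsBundle or a sequence of six radii in [0, 1];
    vertices are placed at the given radii on six rays 60 degrees apart (in
    ``vertex_order``) and the polygon area PA is computed by the shoelace
    formula. PAM = PA normalised by the unit-hexagon area 3*sqrt(3)/2.
    Returns (PA, PAM).
    """
    if isinstance(values, MetricsBundle):
        radii = [getattr(values, name) for name in vertex_order]
        if any(r is None for r in radii):
            missing = [n for n, r in zip(vertex_order, radii) if r is None]
            raise ValueError(f"PAM needs all six metrics; missing {missing}")
    else:
        radii = list(values)
    radii = np.asarray(radii, dtype=float)
    if radii.shape != (6,):
        raise ValueError("PAM needs exactly six radii")
    if np.any(radii < 0) or np.any(radii > 1):
        raise ValueError("PAM radii must lie in [0, 1]")
    angles = np.deg2rad(90.0 - 60.0 * np.arange(6))
    x = radii * np.cos(angles)
    y = radii * np.sin(angles)
    pa = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return float(pa), float(pa / HEXAGON_AREA)


def plot_pam(values, vertex_order=PAM_VERTEX_ORDER, path=None, title=None):
    """Hexagon radar plot of the six PAM metrics (vector graphic export)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(values, MetricsBundle):
        radii = [getattr(values, name) for name in vertex_order]
    else:
        radii = list(values)
    pa, score = pam(radii, vertex_order=vertex_order)
    angles = np.deg2rad(90.0 - 60.0 * np.arange(7))
    r = np.asarray(list(radii) + [radii[0]], dtype=float)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(angles, r, "b-")
    ax.fill(angles, r, alpha=0.25)
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels(vertex_order)
    ax.set_ylim(0, 1)
    ax.set_title(title or f"PAM = {score:.4f}")
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def kfold_indices(n, k=5, seed=0):
    """Seeded shuffled partition of range(n) into k near-equal folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("dataset smaller than the number of folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [order[i::k] for i in range(k)]


def kfold_cv(features, labels, train_fn, predict_fn, k=5, seed=0):
    """k-fold cross-validation of a classifier.

    ``train_fn(X, y, fold_seed) -> model``; ``predict_fn(model, X)`` returns
    predicted labels or (labels, scores). Returns (per-fold bundles, mean
    bundle); AUC is included when scores are provided.
    """
    features = np.asarray(features)
    labels = np.asarray(labels).astype(int)
    folds = kfold_indices(len(labels), k=k, seed=seed)
    bundles = []
    for i, val_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        model = train_fn(features[train_idx], labels[train_idx], seed + i)
        out = predict_fn(model, features[val_idx])
        if isinstance(out, tuple):
            pred, scores = out
        else:
            pred, scores = out, None
        bundle = basic_metrics(ConfusionCounts.from_labels(pred, labels[val_idx]))
        if scores is not None and len(set(labels[val_idx])) == 2:
            bundle.auc = auc(scores, labels[val_idx])
        bundles.append(bundle)
    return bundles, mean_bundle(bundles)


def mean_bundle(bundles):
    """Field-wise arithmetic mean over the defined values of each metric."""
    out = MetricsBundle()
    for f in fields(MetricsBundle):
        if f.name == "undefined":
            continue
        vals = [getattr(b, f.name) for b in bundles if getattr(b, f.name) is not None]
        setattr(out, f.name, float(np.mean(vals)) if vals else None)
    out.undefined = {k for k, v in out.as_dict().items() if v is None}
    return out


def compare_methods(bundle_a, bundle_b, metrics=None):
    """Per-metric absolute deltas (a - b, 4 decimals) and relative
    improvements (100 * (a / b - 1), 2 decimals)."""

    def values(bundle):
        return bundle.as_dict() if isinstance(bundle, MetricsBundle) else dict(bundle)

    a, b = values(bundle_a), values(bundle_b)
    if metrics is None:
        metrics = [
            m for m in a if m in b and a[m] is not None and b[m] is not None
        ]
    out = {}
    for m in metrics:
        if a.get(m) is None or b.get(m) is None:
            raise ValueError(f"metric {m!r} missing from one of the bundles")
        entry = {"delta": round(a[m] - b[m], 4)}
        entry["relative_pct"] = (
            None if b[m] == 0 else round(100.0 * (a[m] / b[m] - 1.0), 2)
        )
        out[m] = entry
    return out


def moisture_ratio(Mt, Mo, Me):
    """Normalised residual moisture (Mt - Me) / (Mo - Me)."""
    if Mo == Me:
        raise ValueError("initial and equilibrium humidity must differ")
    return (Mt - Me) / (Mo - Me)


def metrics_to_json(bundle: MetricsBundle, path):
    with open(path, "w") as fh:
        json.dump(bundle.as_dict(), fh, indent=2)


def metrics_to_csv(bundle: MetricsBundle, path):
    d = bundle.as_dict()
    with open(path, "w") as fh:
        fh.write(",".join(d) + "\n")
        fh.write(
            ",".join("" if v is None else f"{v:.6f}" for v in d.values()) + "\n"
        )
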