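"""Loss functions. Each returns (scalar loss, gradient w.r.t. the logits)."""

from __future__ import annotations

import numpy as np

from .layers import sigmoid


def softmax_ce_loss(logits, labels):
    """Cross-entropy over softmax probabilities; labels are integer classes."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def sigmoid_bce_loss(logits, targets):
    """Element-wise binary cross-entropy on independent sigmoid outputs."""
    p = sigmoid(logits)
    eps = 1e-12
    loss = -(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps)).mean()
    grad = (p - targets) / targets.size
    return loss, grad


def mse_loss(pred, targets):
    diff = pred - targets
    loss = (diff**2).mean()
    return loss, 2.0 * diff / diff.size
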