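"""Generic minibatch training loop."""

from __future__ import annotations

import numpy as np

from .optim import Adam


def fit(
    net,
    X,
    Y,
    loss_fn,
    *,
    epochs=10,
    batch_size=32,
    lr=1e-3,
    betas=(0.9, 0.999),
    rng=None,
    accuracy_fn=None,
):
    """Train ``net`` in place with Adam; returns a per-epoch history.

    ``rng`` drives the (only) stochastic element, the epoch shuffles, so a
    caller seeding it gets bit-identical training runs. ``accuracy_fn``,
    when given, maps (logits, Y) -> scalar and is logged per epoch.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if rng is None:
        rng = np.random.default_rng()
    opt = Adam(net.params(), lr=lr, betas=betas)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = net.forward(X[idx], training=True)
            loss, grad = loss_fn(logits, Y[idx])
            opt.zero_grad()
            net.backward(grad)
            opt.step()
            total += loss * len(idx)
        record = {"epoch": epoch, "loss": total / n}
        if accuracy_fn is not None:
            record["accuracy"] = float(accuracy_fn(net.forward(X), Y))
        history.append(record)
    return history
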