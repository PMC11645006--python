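"""Shared architecture templates for the 32x32-patch models.

Two encoder variants:

* ``"vgg16"`` — the full backbone: 13 convolutions, 13 batch norms and
  5 max-pool layers, reducing a 32x32 patch to 1x1x512.
* ``"reduced"`` — a 3-block encoder with the same structure per block
  (conv / bn / relu / pool) sized so the whole model trains on one CPU
  core in well under a minute; used throughout the test suite.

Both feed a head of flatten, dense, batch norm, ReLU and a final dense
layer producing ``n_out`` values.
"""

from __future__ import annotations

ENCODER_VARIANTS = {
    # per block: (n convs, channels); a pool follows each block
    "vgg16": [(2, 64), (2, 128), (3, 256), (3, 512), (3, 512)],
    "reduced": [(1, 8), (1, 16), (1, 16)],
}

PATCH_SIZE = 32


def _encoder_spec(variant):
    try:
        blocks = ENCODER_VARIANTS[variant]
    except KeyError:
        raise ValueError(
            f"unknown encoder variant {variant!r}; "
            f"choose from {sorted(ENCODER_VARIANTS)}"
        ) from None
    spec = []
    in_ch = 3
    size = PATCH_SIZE
    for n_convs, ch in blocks:
        for _ in range(n_convs):
            spec.append(("conv", in_ch, ch))
            spec.append(("bn", ch))
            spec.append(("relu",))
            in_ch = ch
        spec.append(("pool",))
        size //= 2
    return spec, in_ch * size * size


def build_patch_cnn(variant="reduced", head_hidden=None, n_out=2, rng=None):
    """Full patch model: encoder + flatten/dense/bn/relu + dense(n_out).

    The final dense layer emits raw scores; the loss (softmax CE for
    segmentation, MSE on a scaled target for depth) interprets them.
    """
    from .network import Sequential

    spec, flat = _encoder_spec(variant)
    if head_hidden is None:
        head_hidden = 256 if variant == "vgg16" else 32
    spec = spec + [
        ("flatten",),
        ("dense", flat, head_hidden),
        ("bn", head_hidden),
        ("relu",),
        ("dense", head_hidden, n_out),
    ]
    return Sequential(spec, rng=rng)


def build_mlp(layer_sizes, rng=None):
    """Fully connected ReLU network; final layer is linear (logits)."""
    from .network import Sequential

    spec = []
    for i, (a, b) in enumerate(zip(layer_sizes[:-1], layer_sizes[1:])):
        spec.append(("dense", a, b))
        if i < len(layer_sizes) - 2:
            spec.append(("relu",))
    return Sequential(spec, rng=rng)


def layer_type_counts(net):
    """Mapping of spec kind -> count, for architecture introspection."""
    return {k: net.count(k) for k in ("conv", "bn", "pool", "dense", "relu")}
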