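"""Minimal feedforward-network machinery: forward pass, analytic backprop, Adam.

The impulse-response networks used here are tiny (two hidden layers of a few
dozen tanh units), so the package carries its own dense-layer arithmetic in
numpy rather than depending on a deep-learning framework. Layer ``l`` computes
``f_l(x) = act_l(W_l f_{l-1}(x) + b_l)`` with ``f_0(x) = x``; the output layer
of an impulse-response stack uses the identity activation so convolution
weights are unbounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_ACTIVATIONS = {
    "identity": (lambda h: h, lambda h, a: np.ones_like(a)),
    "tanh": (np.tanh, lambda h, a: 1.0 - a * a),
    "relu": (lambda h: np.maximum(h, 0.0), lambda h, a: (h > 0).astype(h.dtype)),
}


@dataclass
class FeedforwardSpec:
    """Shape of a feedforward stack.

    Attributes
    ----------
    input_dim : int
        Width of the input vector (D_0).
    widths : tuple of int
        Output widths of layers 1..L.
    activations : tuple of str
        One activation name per layer; the final activation of an
        impulse-response stack must be ``"identity"``.
    """

    input_dim: int
    widths: tuple
    activations: tuple = field(default=None)

    def __post_init__(self):
        self.widths = tuple(int(w) for w in self.widths)
        if len(self.widths) < 1:
            raise ValueError("at least one layer is required")
        if any(w < 1 for w in self.widths) or self.input_dim < 1:
            raise ValueError("layer widths must be positive")
        if self.activations is None:
            self.activations = ("tanh",) * (len(self.widths) - 1) + ("identity",)
        self.activations = tuple(self.activations)
        if len(self.activations) != len(self.widths):
            raise ValueError("one activation per layer is required")
        for a in self.activations:
            if a not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")

    @property
    def n_layers(self) -> int:
        return len(self.widths)


def init_ffn(spec: FeedforwardSpec, rng: np.random.Generator, out_scale: float = 1.0):
    """Glorot-uniform weights and zero biases, as ``[(W_1, b_1), ...]``.

    ``out_scale`` shrinks the final layer's weights, which keeps initial
    convolution weights near zero without blocking gradient flow.
    """
    params = []
    d_in = spec.input_dim
    for li, d_out in enumerate(spec.widths):
        lim = np.sqrt(6.0 / (d_in + d_out))
        if li == spec.n_layers - 1:
            lim *= out_scale
        W = rng.uniform(-lim, lim, size=(d_out, d_in))
        b = np.zeros(d_out)
        params.append((W, b))
        d_in = d_out
    return params


def ffn_forward(
    spec: FeedforwardSpec,
    params,
    X: np.ndarray,
    dropout_masks=None,
):
    """Vectorized forward pass over rows of ``X`` (shape ``(n, input_dim)``).

    ``dropout_masks`` is an optional list with one entry per hidden layer
    (``None`` for no dropout on that layer); masks are already inverted
    (scaled by ``1/(1-p)``) so the deterministic pass needs no rescaling.
    Returns ``(out, cache)`` where the cache holds what backprop needs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.input_dim:
        raise ValueError(
            f"input has width {X.shape[1]}, layer 1 expects {spec.input_dim}"
        )
    a = X
    cache = {"inputs": [], "pre": [], "act": [], "masks": dropout_masks}
    for li, ((W, b), name) in enumerate(zip(params, spec.activations)):
        if W.shape != (spec.widths[li], a.shape[1]):
            raise ValueError(f"weight shape mismatch at layer {li + 1}")
        cache["inputs"].append(a)
        h = a @ W.T + b
        act_fn, _ = _ACTIVATIONS[name]
        a = act_fn(h)
        if dropout_masks is not None and li < spec.n_layers - 1:
            m = dropout_masks[li]
            if m is not None:
                a = a * m
        cache["pre"].append(h)
        cache["act"].append(a)
    return a, cache


def ffn_backward(spec: FeedforwardSpec, params, cache, grad_out: np.ndarray):
    """Backprop through :func:`ffn_forward`.

    Returns ``(grads, grad_input)`` with ``grads`` mirroring ``params``.
    """
    grads = [None] * spec.n_layers
    g = np.asarray(grad_out, dtype=float)
    masks = cache["masks"]
    for li in range(spec.n_layers - 1, -1, -1):
        W, _b = params[li]
        name = spec.activations[li]
        _, act_grad = _ACTIVATIONS[name]
        a = cache["act"][li]
        h = cache["pre"][li]
        if masks is not None and li < spec.n_layers - 1 and masks[li] is not None:
            g = g * masks[li]
            # a was stored post-mask; activation derivative needs pre-mask value
            a_pre = _ACTIVATIONS[name][0](h)
            dh = g * act_grad(h, a_pre)
        else:
            dh = g * act_grad(h, a)
        x_in = cache["inputs"][li]
        grads[li] = (dh.T @ x_in, dh.sum(axis=0))
        g = dh @ W
    return grads, g


def ffn_apply(spec: FeedforwardSpec, params, x: np.ndarray) -> np.ndarray:
    """Apply a feedforward stack to a single vector (or batch of rows)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    out, _ = ffn_forward(spec, params, np.atleast_2d(x))
    return out[0] if single else out


def sample_dropout_masks(
    spec: FeedforwardSpec, rate: float, n: int, rng: np.random.Generator
):
    """Inverted dropout masks for the hidden layers, or ``None`` if rate is 0."""
    if rate <= 0.0:
        return None
    keep = 1.0 - rate
    masks = []
    for w in spec.widths[:-1]:
        masks.append((rng.random((n, w)) < keep).astype(float) / keep)
    return masks


class Adam:
    """Adam optimizer over a flat ``dict[str, ndarray]`` parameter store."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for k, g in grads.items():
            if g is None:
                continue
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / corr1
            vhat = self.v[k] / corr2
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
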