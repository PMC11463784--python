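"""The learned oviposition-rate function: a bounded 2-10-10-1 sigmoid MLP.

The oviposition rate (eggs per adult per day) as a joint function of daily
temperature and precipitation is unknown; it is represented by a small
feedforward network with logistic-sigmoid activations at every layer
(including the output) whose final activation is affinely mapped into a
biologically plausible band ``(out_lo, out_hi)``. Inputs are scaled to
[0, 1] over fixed physical ranges (0-40 deg C, 0-200 mm) before entering
the first layer so the sigmoids operate away from saturation.

Implemented directly over numpy with an explicit reverse pass
(:func:`backward`) because the network is trained through an ODE solver by
discretize-then-optimize, which only needs vector-Jacobian products.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["NetParams", "init_net", "forward", "forward_cached", "backward",
           "num_params", "get_flat", "set_flat", "save_net", "load_net"]

LAYER_SIZES = (2, 10, 10, 1)
FORMAT_VERSION = 1


@dataclass
class NetParams:
    """Weights, biases and output bounds of the oviposition network."""

    weights: list = field(default_factory=list)   # W_k, shape (n_out, n_in)
    biases: list = field(default_factory=list)    # b_k, shape (n_out,)
    out_lo: float = 4.0     # baseline oviposition rate (eggs mosquito^-1 day^-1)
    out_hi: float = 20.0    # maximum oviposition rate
    input_ranges: tuple = ((0.0, 40.0), (0.0, 200.0))  # (T, R) scaling ranges

    def __post_init__(self):
        if self.out_hi <= self.out_lo or self.out_lo < 0:
            raise ValueError("require out_hi > out_lo >= 0")
        sizes = [w.shape for w in self.weights]
        expect = [(LAYER_SIZES[k + 1], LAYER_SIZES[k]) for k in range(len(LAYER_SIZES) - 1)]
        if sizes != expect:
            raise ValueError(f"weight shapes {sizes} != expected {expect}")
        for k, b in enumerate(self.biases):
            if b.shape != (LAYER_SIZES[k + 1],):
                raise ValueError("bias shape mismatch")

    def copy(self) -> "NetParams":
        return NetParams([w.copy() for w in self.weights],
                         [b.copy() for b in self.biases],
                         self.out_lo, self.out_hi, self.input_ranges)


def init_net(seed: int, out_lo: float = 4.0, out_hi: float = 20.0) -> NetParams:
    """Reproducible small random initialization: U(+-1/sqrt(fan_in)) weights, zero biases."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for n_in, n_out in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:]):
        bound = 1.0 / np.sqrt(n_in)
        weights.append(rng.uniform(-bound, bound, size=(n_out, n_in)))
        biases.append(np.zeros(n_out))
    return NetParams(weights, biases, out_lo, out_hi)


def _scale_inputs(net: NetParams, T, R) -> np.ndarray:
    """Map (T, R) into [0, 1]^2.

    Temperature is scaled linearly over its physical range. Precipitation is
    log-compressed (log1p) before scaling: daily rainfall is heavy-tailed
    and the oviposition response concentrates at small accumulations, so a
    linear map over 0-200 mm would collapse the informative 0-30 mm band
    into a sliver of the input domain.
    """
    (t_lo, t_hi), (r_lo, r_hi) = net.input_ranges
    T = np.asarray(T, dtype=float)
    R = np.asarray(R, dtype=float)
    r_scaled = np.log1p(np.maximum(R - r_lo, 0.0)) / np.log1p(r_hi - r_lo)
    return np.stack([(T - t_lo) / (t_hi - t_lo), r_scaled], axis=-1)


def forward(net: NetParams, T, R):
    """Oviposition rate at (T, R); scalar in -> scalar out, arrays broadcast."""
    out, _ = forward_cached(net, T, R)
    return out if np.ndim(out) else float(out)


def forward_cached(net: NetParams, T, R):
    """Forward pass returning the activations needed by :func:`backward`."""
    x = _scale_inputs(net, T, R)
    batch_shape = x.shape[:-1]
    a = x.reshape(-1, 2)
    acts = [a]
    for W, b in zip(net.weights, net.biases):
        a = expit(a @ W.T + b)
        acts.append(a)
    out = net.out_lo + (net.out_hi - net.out_lo) * a[:, 0]
    return out.reshape(batch_shape), acts


def backward(net: NetParams, acts: list, grad_out: np.ndarray):
    """VJP of the forward pass: d(loss)/d(weights, biases) given d(loss)/d(output).

    ``acts`` is the cache from :func:`forward_cached`; ``grad_out`` has one
    entry per batch row. Returns (weight grads, bias grads) with the shapes
    of ``net.weights`` / ``net.biases``.
    """
    g = np.asarray(grad_out, dtype=float).reshape(-1, 1)
    delta = g * (net.out_hi - net.out_lo)
    gW = [None] * len(net.weights)
    gb = [None] * len(net.biases)
    for k in range(len(net.weights) - 1, -1, -1):
        a_out, a_in = acts[k + 1], acts[k]
        delta = delta * a_out * (1.0 - a_out)      # through the sigmoid
        gW[k] = delta.T @ a_in
        gb[k] = delta.sum(axis=0)
        if k > 0:
            delta = delta @ net.weights[k]
    return gW, gb


def num_params(net: NetParams) -> int:
    return sum(w.size for w in net.weights) + sum(b.size for b in net.biases)


def get_flat(net: NetParams) -> np.ndarray:
    """Concatenate all weights and biases into one parameter vector."""
    parts = [w.ravel() for w in net.weights] + [b.ravel() for b in net.biases]
    return np.concatenate(parts)


def set_flat(net: NetParams, flat: np.ndarray) -> NetParams:
    """Return a copy of ``net`` with parameters taken from ``flat``."""
    out = net.copy()
    i = 0
    for w in out.weights:
        w[...] = flat[i:i + w.size].reshape(w.shape)
        i += w.size
    for b in out.biases:
        b[...] = flat[i:i + b.size]
        i += b.size
    if i != flat.size:
        raise ValueError(f"flat vector has {flat.size} entries, expected {i}")
    return out


def flat_grads(gW: list, gb: list) -> np.ndarray:
    return np.concatenate([g.ravel() for g in gW] + [g.ravel() for g in gb])


def save_net(net: NetParams, path) -> None:
    """Serialize to a portable JSON file (flat arrays + shapes + bounds)."""
    doc = {
        "format_version": FORMAT_VERSION,
        "layer_sizes": list(LAYER_SIZES),
        "weights": [w.tolist() for w in net.weights],
        "biases": [b.tolist() for b in net.biases],
        "out_lo": net.out_lo,
        "out_hi": net.out_hi,
        "input_ranges": [list(r) for r in net.input_ranges],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_net(path) -> NetParams:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported net format version {doc.get('format_version')}")
    return NetParams(
        [np.asarray(w, dtype=float) for w in doc["weights"]],
        [np.asarray(b, dtype=float) for b in doc["biases"]],
        float(doc["out_lo"]),
        float(doc["out_hi"]),
        tuple(tuple(r) for r in doc["input_ranges"]),
    )
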