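"""Minimal NumPy neural-network primitives for the severity regressor.

Each primitive exposes an explicit forward that returns a cache and a
backward that consumes it, so the encoder in :mod:`madrscore.model` can
assemble exact gradients without an autodiff framework.  Gradient
correctness is pinned down by finite-difference checks in the test
suite.

Also here: decoupled-weight-decay Adam (AdamW), global gradient-norm
clipping, and the linear warmup / linear decay learning-rate schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np
from scipy.special import erf

Params = Dict[str, np.ndarray]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)
_LN_EPS = 1e-12


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) Gaussian error linear unit."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    Phi = 0.5 * (1.0 + erf(x / _SQRT2))
    return Phi + x * phi


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm_forward(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    """Normalize over the last axis; returns (y, cache)."""
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def layer_norm_backward(dy: np.ndarray, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m = dxhat.mean(axis=-1, keepdims=True)
    mx = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m - xhat * mx)
    return dx, dg, db


def linear_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W + b, x


def linear_backward(dy: np.ndarray, x: np.ndarray, W: np.ndarray):
    dW = x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
    db = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
    dx = dy @ W.T
    return dx, dW, db


def clip_global_norm(grads: Params, max_norm: float) -> float:
    """Scale all gradients in place so the global L2 norm is <= max_norm.

    Returns the pre-clipping global norm.
    """
    total = float(np.sqrt(sum(float((g ** 2).sum()) for g in grads.values())))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
    return total


def lr_multiplier(step: int, total_steps: int, warmup_steps: int) -> float:
    """Linear warmup over ``warmup_steps`` then linear decay to 0 at ``total_steps``.

    ``step`` is 1-based (the multiplier for the step about to be taken).
    """
    if total_steps <= 0:
        return 0.0
    warmup_steps = max(0, min(warmup_steps, total_steps))
    if warmup_steps > 0 and step <= warmup_steps:
        return step / warmup_steps
    if total_steps == warmup_steps:
        return 1.0
    return max(0.0, (total_steps - step) / (total_steps - warmup_steps))


@dataclass
class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is applied only to parameters for which
    ``decay_filter(name, param)`` is true (conventionally the 2-D weight
    matrices, excluding biases, LayerNorm parameters and the per-item
    regression heads — see the model module for the filter used there).
    """

    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    decay_filter: Callable[[str, np.ndarray], bool] = lambda name, p: p.ndim >= 2
    _m: Params = field(default_factory=dict, repr=False)
    _v: Params = field(default_factory=dict, repr=False)
    _t: int = field(default=0, repr=False)

    def step(self, params: Params, grads: Params, lr_scale: float = 1.0) -> None:
        self._t += 1
        lr = self.learning_rate * lr_scale
        bc1 = 1.0 - self.beta1 ** self._t
        bc2 = 1.0 - self.beta2 ** self._t
        for name, p in params.items():
            g = grads[name]
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and self.decay_filter(name, p):
                update = update + self.weight_decay * p
            p -= lr * update
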