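"""Minimal differentiable 3-D CNN building blocks on top of autograd.

Everything here operates on plain numpy arrays (or autograd boxes during a
backward pass). The only custom primitive is ``im2col3d`` — patch
extraction for 3-D convolution — whose vector-Jacobian product is the
standard col2im scatter-add, written as a loop over the k^3 kernel offsets
so it stays vectorized over batch, channel and space.

Layers are pure functions of a parameter dict ``{name: ndarray}``; there
is no module object state, which keeps training fully deterministic and
the parameter tree trivially serializable.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "im2col3d",
    "conv3d",
    "group_norm",
    "max_pool3d",
    "global_avg_pool",
    "relu",
    "sigmoid",
    "dense",
    "AdamState",
    "adam_step",
]


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


@primitive
def im2col3d(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Extract all k^3 patches of ``x`` (B, C, D, H, W) as rows.

    Returns an array of shape ``(B, P, C*k^3)`` where P is the number of
    output positions in D-major order, matching a later reshape to
    ``(B, Do, Ho, Wo)``.
    """
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    w = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    w = w[:, :, ::stride, ::stride, ::stride]
    B, C, Do, Ho, Wo = w.shape[:5]
    w = np.ascontiguousarray(w.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    return w.reshape(B, Do * Ho * Wo, C * k * k * k)


def _col2im3d(g, xshape, k, stride, pad):
    B, C, D, H, W = xshape
    Dp, Hp, Wp = D + 2 * pad, H + 2 * pad, W + 2 * pad
    Do, Ho, Wo = ((n - k) // stride + 1 for n in (Dp, Hp, Wp))
    g = g.reshape(B, Do, Ho, Wo, C, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
    out = np.zeros((B, C, Dp, Hp, Wp), dtype=g.dtype)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                out[
                    :,
                    :,
                    i : i + stride * Do : stride,
                    j : j + stride * Ho : stride,
                    l : l + stride * Wo : stride,
                ] += g[..., i, j, l]
    if pad:
        out = out[:, :, pad : pad + D, pad : pad + H, pad : pad + W]
    return out


defvjp(
    im2col3d,
    lambda ans, x, k, stride, pad: lambda g: _col2im3d(g, np.shape(x), k, stride, pad),
)


def conv3d(x, weight, bias, stride: int = 1, pad: int | None = None):
    """3-D convolution. ``weight`` has shape (C_in*k^3, C_out); the kernel
    size is recovered from the weight's first axis. ``pad`` defaults to
    'same'-style (k-1)//2 padding."""
    cin = x.shape[1]
    k = round((weight.shape[0] / cin) ** (1.0 / 3.0))
    assert cin * k**3 == weight.shape[0], "weight shape inconsistent with input channels"
    if pad is None:
        pad = (k - 1) // 2
    B, _, D, H, W = x.shape
    cols = im2col3d(x, k, stride, pad)
    out = anp.matmul(cols, weight) + bias
    Do, Ho, Wo = (_out_size(n, k, stride, pad) for n in (D, H, W))
    out = anp.transpose(out, (0, 2, 1))
    return anp.reshape(out, (B, weight.shape[1], Do, Ho, Wo))


def group_norm(x, gamma, beta, num_groups: int, eps: float = 1e-5):
    """Group normalization over (channel-group, D, H, W).

    Chosen over batch norm so that evaluation is independent of batch
    composition and no running statistics need to be tracked — forward
    passes are bit-stable and single-sample batches are well-defined.
    """
    B, C, D, H, W = x.shape
    G = num_groups
    xg = anp.reshape(x, (B, G, C // G, D, H, W))
    mu = anp.mean(xg, axis=(2, 3, 4, 5), keepdims=True)
    var = anp.mean((xg - mu) ** 2, axis=(2, 3, 4, 5), keepdims=True)
    xn = (xg - mu) / anp.sqrt(var + eps)
    xn = anp.reshape(xn, (B, C, D, H, W))
    return xn * anp.reshape(gamma, (1, C, 1, 1, 1)) + anp.reshape(beta, (1, C, 1, 1, 1))


def max_pool3d(x, k: int = 3, stride: int = 2, pad: int = 1):
    """Max pooling via per-channel patch extraction."""
    B, C, D, H, W = x.shape
    xr = anp.reshape(x, (B * C, 1, D, H, W))
    cols = im2col3d(xr, k, stride, pad)
    pooled = anp.max(cols, axis=2)
    Do, Ho, Wo = (_out_size(n, k, stride, pad) for n in (D, H, W))
    return anp.reshape(pooled, (B, C, Do, Ho, Wo))


def global_avg_pool(x):
    """Spatial mean of a (B, C, D, H, W) map -> (B, C)."""
    return anp.mean(x, axis=(2, 3, 4))


def relu(x):
    return anp.maximum(x, 0.0)


def sigmoid(x):
    return 1.0 / (1.0 + anp.exp(-x))


def dense(x, weight, bias):
    return anp.matmul(x, weight) + bias


class AdamState:
    """First/second-moment accumulators for Adam over a parameter dict."""

    def __init__(self, params: dict):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0


def adam_step(
    params: dict,
    grads: dict,
    state: AdamState,
    lr: float = 1e-3,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> dict:
    """One Adam update; returns a new parameter dict, mutates ``state``."""
    state.t += 1
    t = state.t
    out = {}
    for key, p in params.items():
        g = grads[key]
        state.m[key] = beta1 * state.m[key] + (1 - beta1) * g
        state.v[key] = beta2 * state.v[key] + (1 - beta2) * g * g
        mhat = state.m[key] / (1 - beta1**t)
        vhat = state.v[key] / (1 - beta2**t)
        out[key] = p - lr * mhat / (np.sqrt(vhat) + eps)
    return out
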