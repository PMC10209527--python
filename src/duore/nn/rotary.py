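"""Rotary position mixing shared by attention and the span-scoring heads.

A vector at position m has each feature pair (x[2k], x[2k+1]) rotated by
m * theta_k with theta_k = base^(-2k/d).  Dot products between two rotated
vectors then depend on positions only through their difference, which makes
relative addressing learnable and span scores translation-equivariant.

Rotated vectors are laid out as (even half, odd half) rather than
interleaved; the layout cancels in dot products as long as both sides share
it.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = ["rotary_angles", "apply_rotary"]

_CACHE: dict = {}


def rotary_angles(n: int, d: int, base: float = 10000.0) -> tuple[np.ndarray, np.ndarray]:
    """cos/sin tables of shape (n, d // 2)."""
    key = (n, d, base)
    if key not in _CACHE:
        half = d // 2
        theta = base ** (-2.0 * np.arange(half) / d)
        ang = np.arange(n)[:, None] * theta[None, :]
        _CACHE[key] = (np.cos(ang).astype(np.float32), np.sin(ang).astype(np.float32))
    return _CACHE[key]


def apply_rotary(x: Tensor, base: float = 10000.0) -> Tensor:
    """Rotate the last axis of (..., n, d) by position along the second-last
    axis; d must be even.  Single fused graph node (the backward pass is the
    inverse rotation)."""
    n, d = x.shape[-2], x.shape[-1]
    if d % 2:
        raise ValueError("rotary dimension must be even")
    cos, sin = rotary_angles(n, d, base)
    half = d // 2
    xd = x.data
    xe, xo = xd[..., 0::2], xd[..., 1::2]
    out_data = np.concatenate([xe * cos - xo * sin, xe * sin + xo * cos], axis=-1)

    def bw(g):
        ge, go = g[..., :half], g[..., half:]
        grad = np.empty_like(xd)
        grad[..., 0::2] = ge * cos + go * sin
        grad[..., 1::2] = -ge * sin + go * cos
        x._accum(grad)

    return x._make(out_data, (x,), bw)
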