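"""Fused loss primitives with analytic gradients.

These compute the same values as composing elementary autograd ops, but in
single graph nodes: binary cross-entropy on logits (gradient sigma(x) - y)
and the symmetric KL between two Bernoulli heads (the R-Drop consistency
term).  Both support a non-negative weight array and normalise by the weight
sum.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["bce_with_logits", "bernoulli_sym_kl"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _prep_weights(shape, weights) -> tuple[np.ndarray | None, float]:
    if weights is None:
        return None, float(np.prod(shape))
    w = np.asarray(weights, dtype=np.float32)
    total = float(w.sum())
    if total <= 0:
        raise ValueError("weights must select at least one unit")
    return w, total


def bce_with_logits(scores: Tensor, labels, weights=None) -> Tensor:
    """(Weighted) mean of -[y log sigma(x) + (1-y) log(1 - sigma(x))]."""
    x = scores.data
    y = np.asarray(labels, dtype=x.dtype)
    w, total = _prep_weights(x.shape, weights)
    # stable: relu(x) - x y + log(1 + exp(-|x|))
    unit = np.maximum(x, 0.0) - x * y + np.log1p(np.exp(-np.abs(x)))
    value = (unit if w is None else unit * w).sum() / total

    def bw(g):
        grad = (_sigmoid(x) - y) / total
        if w is not None:
            grad = grad * w
        scores._accum(g * grad)

    return scores._make(np.asarray(value, dtype=x.dtype), (scores,), bw)


def bernoulli_sym_kl(scores1: Tensor, scores2: Tensor, weights=None) -> Tensor:
    """(Weighted) mean of 1/2 [KL(p1 || p2) + KL(p2 || p1)] for per-unit
    Bernoulli distributions given by two logit arrays."""
    x1, x2 = scores1.data, scores2.data
    w, total = _prep_weights(x1.shape, weights)
    s1, s2 = _sigmoid(x1), _sigmoid(x2)
    # log p = -softplus(-x), log(1-p) = -softplus(x)
    lp1, lp2 = -np.logaddexp(0.0, -x1), -np.logaddexp(0.0, -x2)
    lq1, lq2 = -np.logaddexp(0.0, x1), -np.logaddexp(0.0, x2)
    kl12 = s1 * (lp1 - lp2) + (1.0 - s1) * (lq1 - lq2)
    kl21 = s2 * (lp2 - lp1) + (1.0 - s2) * (lq2 - lq1)
    unit = 0.5 * (kl12 + kl21)
    value = (unit if w is None else unit * w).sum() / total

    def bw(g):
        g1 = 0.5 * (s1 * (1.0 - s1) * (x1 - x2) + (s1 - s2)) / total
        g2 = 0.5 * (s2 * (1.0 - s2) * (x2 - x1) + (s2 - s1)) / total
        if w is not None:
            g1, g2 = g1 * w, g2 * w
        if scores1.requires_grad:
            scores1._accum(g * g1)
        if scores2.requires_grad:
            scores2._accum(g * g2)

    out = scores1._make(np.asarray(value, dtype=x1.dtype), (scores1, scores2), bw)
    return out
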