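"""Global-pointer span scoring with rotary relative positions, and entity
recognition over a shared encoder.

Every candidate span [h, t] of a sequence receives a bilinear score between a
projected start vector and a projected end vector, each rotated by its
position:  M[h, t] = (W1 v_h + b1)^T R_h^T R_t (W2 v_t + b2).  Because
R_h^T R_t depends only on t - h, the score is relative-position equivariant,
and because every (h, t) cell is scored independently, nested spans are
representable.  Span detection is a per-cell binary decision via the logistic
function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datamodel import Document, EntitySpan
from .encoding import Encoder
from .nn import Linear, Module, Tensor
from .nn.rotary import apply_rotary

__all__ = ["GPHead", "span_scores", "decode_spans", "ERModel", "sigmoid_np"]

DEFAULT_MAX_SPAN_LEN = 40


def sigmoid_np(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class GPHead(Module):
    """Two projections plus rotary position mixing for span scoring."""

    def __init__(self, d: int, d_head: int, rng: np.random.Generator, base: float = 10000.0):
        if d_head % 2:
            raise ValueError("rotary head dimension must be even")
        self.proj_start = Linear(d, d_head, rng)
        self.proj_end = Linear(d, d_head, rng)
        self.d_head = d_head
        self.base = base

    def __call__(self, vectors: Tensor) -> Tensor:
        """Score all (h, t) cells.  vectors: (..., n, d) -> (..., n, n)."""
        q = apply_rotary(self.proj_start(vectors), self.base)
        k = apply_rotary(self.proj_end(vectors), self.base)
        return q @ k.swapaxes(-1, -2)


def span_scores(vectors: Tensor, head: GPHead) -> np.ndarray:
    """Raw score matrix M (n x n) for one sequence; cells with h > t are
    meaningless by convention and left as computed."""
    out = head(vectors)
    return out.data if out.ndim == 2 else out.data[0]


def decode_spans(
    M: np.ndarray,
    threshold: float,
    max_span_len: int = DEFAULT_MAX_SPAN_LEN,
    tokens: Optional[Sequence[str]] = None,
) -> set[EntitySpan]:
    """All spans with h <= t, length <= max_span_len and logistic(M[h,t]) >=
    threshold.  Equivalent to exhaustive enumeration of every cell."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    M = np.asarray(M, dtype=np.float64)
    n = M.shape[0]
    probs = sigmoid_np(M)
    lengths = np.arange(n)[None, :] - np.arange(n)[:, None] + 1  # t - h + 1
    valid = (lengths >= 1) & (lengths <= max_span_len) & (probs >= threshold)
    spans = set()
    for h, t in np.argwhere(valid):
        surface = "".join(tokens[h : t + 1]) if tokens is not None else ""
        spans.add(EntitySpan(int(h), int(t), surface))
    return spans


@dataclass
class ERModel:
    """Entity recognition: shared encoder with separate subject/object heads."""

    encoder: Encoder
    subject_head: GPHead
    object_head: GPHead
    max_span_len: int = DEFAULT_MAX_SPAN_LEN

    @classmethod
    def build(cls, tokenizer, enc_cfg, rng: np.random.Generator, d_head: int = 64,
              max_span_len: int = DEFAULT_MAX_SPAN_LEN) -> "ERModel":
        return cls(
            Encoder(tokenizer, enc_cfg, rng),
            GPHead(enc_cfg.d, d_head, rng),
            GPHead(enc_cfg.d, d_head, rng),
            max_span_len,
        )

    def parameters(self) -> dict:
        return {
            **{f"enc.{k}": v for k, v in self.encoder.net.parameters().items()},
            **{f"subj.{k}": v for k, v in self.subject_head.parameters().items()},
            **{f"obj.{k}": v for k, v in self.object_head.parameters().items()},
        }

    def content_vectors(self, doc: Document, train_mode: bool = False,
                        rng: np.random.Generator | None = None) -> Tensor:
        tokens = self.encoder.tokenizer.tokenize(doc.text, wrap=True, max_len=self.encoder.cfg.max_len)
        vectors = self.encoder.encode_tokens(tokens, train_mode=train_mode, rng=rng)
        return vectors[1 : len(tokens) - 1]  # drop [CLS]/[SEP]

    def score(self, doc: Document) -> tuple[np.ndarray, np.ndarray]:
        """Raw subject and object score matrices in document coordinates."""
        vectors = self.content_vectors(doc)
        return span_scores(vectors, self.subject_head), span_scores(vectors, self.object_head)

    def extract(self, doc: Document, threshold_a: float) -> tuple[set[EntitySpan], set[EntitySpan]]:
        ms, mo = self.score(doc)
        n = min(doc.n, ms.shape[0])
        toks = doc.tokens[:n]
        return (
            decode_spans(ms, threshold_a, self.max_span_len, toks),
            decode_spans(mo, threshold_a, self.max_span_len, toks),
        )
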