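"""Neural building blocks: linear maps, embeddings, multi-head attention and
pre-norm transformer blocks, all on the :mod:`duore.nn.autograd` engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .rotary import apply_rotary

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "TransformerLayer",
    "TransformerEncoder",
]


class Module:
    """Minimal parameter container with named sub-modules."""

    def parameters(self) -> dict:
        params: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                params[name] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    params[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = p
        return params

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            p.data[...] = state[k]

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return (rng.standard_normal((fan_in, fan_out)) * scale).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(_xavier(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator, scale: float = 0.02):
        self.W = Tensor((rng.standard_normal((n, d)) * scale).astype(np.float32), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.W[np.asarray(ids, dtype=np.intp)]


class MultiHeadAttention(Module):
    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        if d % heads:
            raise ValueError("hidden size must be divisible by head count")
        self.heads = heads
        self.dk = d // heads
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.out = Linear(d, d, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None) -> Tensor:
        # x: (B, n, d); mask: (B, n) with 1 for real tokens
        B, n, d = x.shape

        def split(t: Tensor) -> Tensor:  # -> (B, heads, n, dk)
            return t.reshape(B, n, self.heads, self.dk).swapaxes(1, 2)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        # rotary q/k mixing gives content-independent relative addressing
        q, k = apply_rotary(q), apply_rotary(k)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dk))
        if mask is not None:
            bias = np.where(mask[:, None, None, :] > 0, 0.0, -1e9).astype(np.float32)
            scores = scores + Tensor(bias)
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape(B, n, d)
        return self.out(ctx)


class TransformerLayer(Module):
    def __init__(self, d: int, heads: int, d_ffn: int, rng: np.random.Generator):
        self.attn = MultiHeadAttention(d, heads, rng)
        self.ffn1 = Linear(d, d_ffn, rng)
        self.ffn2 = Linear(d_ffn, d, rng)
        self.g1 = Tensor(np.ones(d, dtype=np.float32), requires_grad=True)
        self.b1 = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)
        self.g2 = Tensor(np.ones(d, dtype=np.float32), requires_grad=True)
        self.b2 = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)

    def __call__(self, x, mask, dropout: float, rng: np.random.Generator | None):
        h = x.layer_norm() * self.g1 + self.b1
        a = self.attn(h, mask)
        if rng is not None and dropout > 0:
            a = a.dropout(dropout, rng)
        x = x + a
        h = x.layer_norm() * self.g2 + self.b2
        f = self.ffn2(self.ffn1(h).relu())
        if rng is not None and dropout > 0:
            f = f.dropout(dropout, rng)
        return x + f


class TransformerEncoder(Module):
    """Compact pre-norm transformer producing one d-vector per input token."""

    def __init__(self, vocab_size: int, d: int, layers: int, heads: int,
                 d_ffn: int, max_len: int, rng: np.random.Generator):
        self.tok = Embedding(vocab_size, d, rng)
        self.pos = Embedding(max_len, d, rng)
        self.blocks = [TransformerLayer(d, heads, d_ffn, rng) for _ in range(layers)]
        self.gout = Tensor(np.ones(d, dtype=np.float32), requires_grad=True)
        self.bout = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)
        self.max_len = max_len
        self.d = d

    def __call__(self, ids: np.ndarray, mask: np.ndarray | None = None,
                 dropout: float = 0.0, rng: np.random.Generator | None = None) -> Tensor:
        ids = np.asarray(ids, dtype=np.intp)
        if ids.ndim == 1:
            ids = ids[None, :]
        B, n = ids.shape
        if n > self.max_len:
            raise ValueError(f"sequence length {n} exceeds max_len {self.max_len}")
        x = self.tok(ids) + self.pos(np.arange(n, dtype=np.intp))
        for blk in self.blocks:
            x = blk(x, mask, dropout, rng)
        return x.layer_norm() * self.gout + self.bout
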