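"""Tokenization and contextual token encoding shared by all model heads.

The default backend is a from-scratch compact transformer (character
vocabulary, learned positions, pre-norm blocks); the framework itself is
encoder-agnostic and any module satisfying the same one-vector-per-token
contract can stand in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .nn import Tensor, TransformerEncoder

__all__ = [
    "CLS", "SEP", "UNK", "PAD", "S_OPEN", "S_CLOSE", "O_OPEN", "O_CLOSE",
    "SEP1", "SEP2", "SEP3", "SPECIALS",
    "CharTokenizer", "EncoderConfig", "Encoder",
]

PAD = "[PAD]"
UNK = "[UNK]"
CLS = "[CLS]"
SEP = "[SEP]"
S_OPEN = "[s]"
S_CLOSE = "[/s]"
O_OPEN = "[o]"
O_CLOSE = "[/o]"
SEP1 = "[/s1]"
SEP2 = "[/s2]"
SEP3 = "[/s3]"

#: reserved single-id tokens, never split
SPECIALS = (PAD, UNK, CLS, SEP, S_OPEN, S_CLOSE, O_OPEN, O_CLOSE, SEP1, SEP2, SEP3)


class CharTokenizer:
    """Lossless character tokenizer with reserved special tokens.

    One content token per character; the token index of content token i inside
    an unwrapped sequence equals character offset i, so span coordinates and
    character offsets coincide.
    """

    def __init__(self, charset: Iterable[str]):
        self.vocab: dict[str, int] = {tok: i for i, tok in enumerate(SPECIALS)}
        for ch in sorted(set(charset)):
            if len(ch) != 1:
                raise ValueError(f"charset entries must be single characters, got {ch!r}")
            self.vocab.setdefault(ch, len(self.vocab))
        self.unk_id = self.vocab[UNK]
        self.pad_id = self.vocab[PAD]

    @classmethod
    def from_texts(cls, texts: Iterable[str]) -> "CharTokenizer":
        charset = set()
        for t in texts:
            charset.update(t)
        return cls(charset)

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    def tokenize(self, text: str, wrap: bool = False, max_len: int | None = None) -> list[str]:
        tokens = list(text)
        if max_len is not None:
            reserve = 2 if wrap else 0
            if len(tokens) > max_len - reserve:
                tokens = tokens[: max_len - reserve]
        if wrap:
            tokens = [CLS, *tokens, SEP]
        return tokens

    def to_ids(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.vocab.get(t, self.unk_id) for t in tokens], dtype=np.intp)


@dataclass(frozen=True)
class EncoderConfig:
    backend: str = "tiny"
    layers: int = 2
    d: int = 64
    heads: int = 4
    d_ffn: int = 128
    dropout: float = 0.1
    max_len: int = 256

    def __post_init__(self):
        if self.d % self.heads:
            raise ValueError("d must be divisible by heads")


class Encoder:
    """Tokenizer + compact transformer producing one d-vector per token."""

    def __init__(self, tokenizer: CharTokenizer, cfg: EncoderConfig, rng: np.random.Generator):
        if cfg.backend != "tiny":
            raise ValueError(f"unsupported encoder backend {cfg.backend!r}")
        self.tokenizer = tokenizer
        self.cfg = cfg
        self.net = TransformerEncoder(
            tokenizer.vocab_size, cfg.d, cfg.layers, cfg.heads, cfg.d_ffn, cfg.max_len, rng
        )

    def encode_ids(
        self,
        ids: np.ndarray,
        mask: np.ndarray | None = None,
        train_mode: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Encode a (B, n) or (n,) id array into (B, n, d) vectors.

        Eval mode (train_mode=False) is deterministic; train mode applies
        dropout driven by `rng`.
        """
        dropout = self.cfg.dropout if train_mode else 0.0
        return self.net(ids, mask=mask, dropout=dropout, rng=rng if train_mode else None)

    def encode_tokens(self, tokens: Sequence[str], train_mode: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
        ids = self.tokenizer.to_ids(tokens)
        return self.encode_ids(ids, train_mode=train_mode, rng=rng)[0]


def pad_batch(seqs: list[np.ndarray], pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad id sequences into (B, n) ids plus a 0/1 validity mask."""
    n = max(len(s) for s in seqs)
    ids = np.full((len(seqs), n), pad_id, dtype=np.intp)
    mask = np.zeros((len(seqs), n), dtype=np.float32)
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = s
        mask[i, : len(s)] = 1.0
    return ids, mask
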