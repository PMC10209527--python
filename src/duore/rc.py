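"""Relation classification over marker-highlighted subject–object pairs.

The candidate pair is highlighted in the token sequence by four reserved
boundary tokens [s] … [/s] and [o] … [/o]; the encoder vectors at the two
opening markers are concatenated and fed to a two-layer feed-forward
classifier that emits one logistic score per schema relation (multi-label, so
one pair can carry several relations — the entity-pair-overlap case).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Document, EntitySpan, RelationSchema
from .encoding import CLS, Encoder, O_CLOSE, O_OPEN, S_CLOSE, S_OPEN, SEP
from .er_span import sigmoid_np
from .nn import Linear, Module, Tensor, concat

__all__ = ["MarkedSequence", "insert_markers", "RCModel"]


@dataclass(frozen=True)
class MarkedSequence:
    """Token sequence with the four marker tokens inserted.

    ``marker_positions`` maps each marker token to its index in ``tokens``;
    removing the four markers restores the original sequence exactly.
    """

    tokens: tuple
    marker_positions: dict

    def strip_markers(self) -> list:
        markers = set(self.marker_positions.values())
        return [t for i, t in enumerate(self.tokens) if i not in markers]


def insert_markers(doc: Document, s: EntitySpan, o: EntitySpan) -> MarkedSequence:
    """Insert [s]/[/s] around the subject span and [o]/[/o] around the object.

    Markers land immediately before the start token and immediately after the
    end token.  At a shared boundary, closing markers precede opening ones;
    between two openers the longer-reaching span opens first, and between two
    closers the later-starting (inner) span closes first, so nested spans
    interleave as [s] … [o] … [/o] … [/s].
    """
    for span in (s, o):
        if span.t >= doc.n:
            raise ValueError(f"span {span.key()} out of range for document of {doc.n} tokens")

    # markers at boundary p, with sort ranks realizing the order above
    events = []  # (position, phase, rank, token)
    events.append((s.h, 1, -s.t, S_OPEN))
    events.append((s.t + 1, 0, -s.h, S_CLOSE))
    events.append((o.h, 1, -o.t, O_OPEN))
    events.append((o.t + 1, 0, -o.h, O_CLOSE))
    events.sort()

    out: list = []
    positions: dict = {}
    ei = 0
    for p in range(doc.n + 1):
        while ei < len(events) and events[ei][0] == p:
            positions[events[ei][3]] = len(out)
            out.append(events[ei][3])
            ei += 1
        if p < doc.n:
            out.append(doc.tokens[p])
    return MarkedSequence(tuple(out), positions)


class PairClassifier(Module):
    def __init__(self, d: int, hidden: int, n_relations: int, rng: np.random.Generator):
        self.fc1 = Linear(2 * d, hidden, rng)
        self.fc2 = Linear(hidden, n_relations, rng)

    def __call__(self, v_s: Tensor, v_o: Tensor) -> Tensor:
        return self.fc2(self.fc1(concat([v_s, v_o], axis=-1)).relu())


@dataclass
class RCModel:
    encoder: Encoder
    classifier: PairClassifier
    schema: RelationSchema

    @classmethod
    def build(cls, tokenizer, enc_cfg, schema: RelationSchema,
              rng: np.random.Generator, hidden: int = 128) -> "RCModel":
        return cls(
            Encoder(tokenizer, enc_cfg, rng),
            PairClassifier(enc_cfg.d, hidden, schema.l, rng),
            schema,
        )

    def parameters(self) -> dict:
        return {
            **{f"enc.{k}": v for k, v in self.encoder.net.parameters().items()},
            **{f"clf.{k}": v for k, v in self.classifier.parameters().items()},
        }

    def logits(self, marked: MarkedSequence, train_mode: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        tokens = [CLS, *marked.tokens, SEP]
        vectors = self.encoder.encode_tokens(tokens, train_mode=train_mode, rng=rng)
        v_s = vectors[marked.marker_positions[S_OPEN] + 1]
        v_o = vectors[marked.marker_positions[O_OPEN] + 1]
        return self.classifier(v_s, v_o)

    def classify_pair(self, marked: MarkedSequence) -> np.ndarray:
        """Per-relation probabilities (length l, each in [0, 1])."""
        return sigmoid_np(self.logits(marked).data)

    def classify_pairs(self, doc: Document, pairs, chunk: int = 64) -> np.ndarray:
        """Batched per-relation probabilities for many (s, o) pairs of one
        document; identical to per-pair classification."""
        from .encoding import pad_batch

        if not pairs:
            return np.zeros((0, self.schema.l))
        tok = self.encoder.tokenizer
        out = []
        for lo in range(0, len(pairs), chunk):
            seqs, s_pos, o_pos = [], [], []
            for s, o in pairs[lo : lo + chunk]:
                marked = insert_markers(doc, s, o)
                seqs.append(tok.to_ids([CLS, *marked.tokens, SEP]))
                s_pos.append(marked.marker_positions[S_OPEN] + 1)
                o_pos.append(marked.marker_positions[O_OPEN] + 1)
            ids, mask = pad_batch(seqs, tok.pad_id)
            vectors = self.encoder.net(ids, mask=mask)
            rows = np.arange(len(seqs))
            v_s = vectors[rows, np.asarray(s_pos)]
            v_o = vectors[rows, np.asarray(o_pos)]
            out.append(sigmoid_np(self.classifier(v_s, v_o).data))
        return np.concatenate(out, axis=0)
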