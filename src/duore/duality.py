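"""Reverse-direction extraction: given a relation, find its subject and
object sets.

A prompt rendered from the relation's schema entry (its relation-type,
subject-type and object-type names, joined by the reserved separators [/s1],
[/s2], [/s3]) is prefixed to the text; two global-pointer heads then score
spans over the text region only.  Conditioning on the relation lets this
module act as a self-check on the forward direction: a candidate triplet's
arguments should reappear in the sets extracted for the candidate's own
relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import Document, EntitySpan, RelationSchema, SchemaEntry
from .encoding import CLS, Encoder, SEP, SEP1, SEP2, SEP3
from .er_span import DEFAULT_MAX_SPAN_LEN, GPHead, decode_spans, span_scores
from .nn import Tensor

__all__ = ["Prompt", "DualitySets", "build_prompt", "DLModel"]

#: the five prompt layouts; {rtype}/{stype}/{otype} are type-name token runs
PROMPT_TEMPLATES = {
    1: ("rtype",),
    2: ("stype", "otype"),
    3: ("rtype", "stype"),
    4: ("rtype", "otype"),
    5: ("rtype", "stype", "otype"),
}
_SEPARATORS = (SEP1, SEP2, SEP3)

DEFAULT_TEMPLATE_ID = 5


@dataclass(frozen=True)
class Prompt:
    template_id: int
    tokens: tuple

    @property
    def offset(self) -> int:
        """Tokens preceding document text once assembled: [CLS] P [SEP]."""
        return len(self.tokens) + 2


def build_prompt(template_id: int, entry: SchemaEntry) -> Prompt:
    if template_id not in PROMPT_TEMPLATES:
        raise ValueError(f"template_id must be 1..5, got {template_id}")
    tokens: list[str] = []
    for i, slot in enumerate(PROMPT_TEMPLATES[template_id]):
        tokens.append(_SEPARATORS[i])
        tokens.extend(getattr(entry, slot))  # type names tokenize per character
    return Prompt(template_id, tuple(tokens))


@dataclass
class DualitySets:
    """Per-relation reverse-extracted subject and object sets (S', O')."""

    sets: dict = field(default_factory=dict)  # relation -> (set[EntitySpan], set[EntitySpan])

    def subjects(self, relation: str) -> set[EntitySpan]:
        return self.sets.get(relation, (set(), set()))[0]

    def objects(self, relation: str) -> set[EntitySpan]:
        return self.sets.get(relation, (set(), set()))[1]

    def pooled(self) -> tuple[set[EntitySpan], set[EntitySpan]]:
        subs: set[EntitySpan] = set()
        objs: set[EntitySpan] = set()
        for s, o in self.sets.values():
            subs |= s
            objs |= o
        return subs, objs


@dataclass
class DLModel:
    encoder: Encoder
    subject_head: GPHead
    object_head: GPHead
    schema: RelationSchema
    template_id: int = DEFAULT_TEMPLATE_ID
    max_span_len: int = DEFAULT_MAX_SPAN_LEN

    @classmethod
    def build(cls, tokenizer, enc_cfg, schema: RelationSchema, rng: np.random.Generator,
              d_head: int = 64, template_id: int = DEFAULT_TEMPLATE_ID,
              max_span_len: int = DEFAULT_MAX_SPAN_LEN) -> "DLModel":
        return cls(
            Encoder(tokenizer, enc_cfg, rng),
            GPHead(enc_cfg.d, d_head, rng),
            GPHead(enc_cfg.d, d_head, rng),
            schema,
            template_id,
            max_span_len,
        )

    def parameters(self) -> dict:
        return {
            **{f"enc.{k}": v for k, v in self.encoder.net.parameters().items()},
            **{f"subj.{k}": v for k, v in self.subject_head.parameters().items()},
            **{f"obj.{k}": v for k, v in self.object_head.parameters().items()},
        }

    def assemble(self, doc: Document, relation: str) -> tuple[list, int]:
        """[CLS] Prompt [SEP] text [SEP] plus the text-region offset."""
        prompt = build_prompt(self.template_id, self.schema[relation])
        tokens = [CLS, *prompt.tokens, SEP, *doc.tokens, SEP]
        if len(tokens) > self.encoder.cfg.max_len:
            raise ValueError(
                f"assembled sequence of {len(tokens)} tokens exceeds max_len {self.encoder.cfg.max_len}"
            )
        return tokens, prompt.offset

    def text_vectors(self, doc: Document, relation: str, train_mode: bool = False,
                     rng: np.random.Generator | None = None) -> Tensor:
        tokens, offset = self.assemble(doc, relation)
        vectors = self.encoder.encode_tokens(tokens, train_mode=train_mode, rng=rng)
        return vectors[offset : offset + doc.n]

    def score(self, doc: Document, relation: str) -> tuple[np.ndarray, np.ndarray]:
        """Raw S'/O' score matrices, already in document coordinates."""
        vectors = self.text_vectors(doc, relation)
        return span_scores(vectors, self.subject_head), span_scores(vectors, self.object_head)

    def score_many(self, doc: Document, relations) -> dict:
        """Batched raw S'/O' matrices for several relations of one document;
        identical to per-relation scoring (prompts of equal length share one
        forward pass)."""
        from .encoding import pad_batch

        relations = sorted(set(relations))
        out: dict = {}
        groups: dict = {}
        for rel in relations:
            tokens, offset = self.assemble(doc, rel)
            groups.setdefault(offset, []).append((rel, tokens))
        tok = self.encoder.tokenizer
        for offset, items in groups.items():
            ids, mask = pad_batch([tok.to_ids(tokens) for _, tokens in items], tok.pad_id)
            vectors = self.encoder.net(ids, mask=mask)
            text = vectors[:, offset : offset + doc.n, :]
            ms = self.subject_head(text).data
            mo = self.object_head(text).data
            for i, (rel, _) in enumerate(items):
                out[rel] = (ms[i], mo[i])
        return out

    def dual_extract(self, doc: Document, relation: str,
                     threshold_c: float) -> tuple[set[EntitySpan], set[EntitySpan]]:
        ms, mo = self.score(doc, relation)
        return (
            decode_spans(ms, threshold_c, self.max_span_len, doc.tokens),
            decode_spans(mo, threshold_c, self.max_span_len, doc.tokens),
        )
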