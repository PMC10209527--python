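"""Core domain types for triplet extraction.

A document is a tokenized text ``c1..cn``; entities are inclusive token spans
``[h, t]``; a fact is an ordered (subject, relation, object) triplet whose
relation belongs to a fixed schema.  Candidate triplets additionally carry the
scores produced along the forward (entity-pair -> relation) direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "EntitySpan",
    "Triplet",
    "CandidateTriplet",
    "RelationSchema",
    "SchemaEntry",
    "Document",
    "Corpus",
    "enumerate_pairs",
    "normalize_triplet",
]


@dataclass(frozen=True, order=True)
class EntitySpan:
    """Inclusive token span [h, t] with its covered surface text."""

    h: int
    t: int
    surface: str
    etype: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        if self.h > self.t:
            raise ValueError(f"span start {self.h} after end {self.t}")
        if self.h < 0:
            raise ValueError(f"negative span start {self.h}")

    @property
    def length(self) -> int:
        return self.t - self.h + 1

    def key(self) -> tuple[int, int]:
        return (self.h, self.t)


@dataclass(frozen=True)
class Triplet:
    s: EntitySpan
    r: str
    o: EntitySpan

    def __post_init__(self):
        if self.s.key() == self.o.key():
            raise ValueError("subject and object must not be the identical span")


@dataclass(frozen=True)
class CandidateTriplet:
    """A triplet proposed by the forward direction, with its scores.

    ``gamma_rc`` is the relation-classifier probability of the candidate's own
    relation; ``s_score``/``o_score`` are the span-detection probabilities.
    """

    triplet: Triplet
    gamma_rc: float
    s_score: float = 1.0
    o_score: float = 1.0

    def __post_init__(self):
        for name in ("gamma_rc", "s_score", "o_score"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class SchemaEntry:
    relation: str
    rtype: str
    stype: str
    otype: str


class RelationSchema:
    """Fixed inventory of l relations with their type signature."""

    def __init__(self, entries: Iterable[SchemaEntry]):
        self.entries: list[SchemaEntry] = list(entries)
        labels = [e.relation for e in self.entries]
        if len(labels) != len(set(labels)):
            raise ValueError("relation labels must be unique")
        self._by_label = {e.relation: e for e in self.entries}

    @property
    def l(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e.relation for e in self.entries]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def __getitem__(self, label: str) -> SchemaEntry:
        return self._by_label[label]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, RelationSchema) and self.entries == other.entries


@dataclass
class Document:
    doc_id: str
    text: str
    tokens: list[str]
    language: str = "synthetic"
    gold: Optional[set] = None  # set[Triplet]
    locate_failures: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.tokens)

    def validate(self) -> None:
        for t in self.gold or ():
            for span in (t.s, t.o):
                if not (0 <= span.h <= span.t < self.n):
                    raise ValueError(f"{self.doc_id}: span {span.key()} outside document of {self.n} tokens")
                covered = "".join(self.tokens[span.h : span.t + 1])
                if covered != span.surface:
                    raise ValueError(
                        f"{self.doc_id}: span {span.key()} covers {covered!r}, surface says {span.surface!r}"
                    )


@dataclass
class Corpus:
    documents: list[Document]
    schema: RelationSchema
    split: str = "train"

    def __post_init__(self):
        for doc in self.documents:
            for t in doc.gold or ():
                if t.r not in self.schema:
                    raise ValueError(f"{doc.doc_id}: relation {t.r!r} missing from schema")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)


def enumerate_pairs(
    subjects: Iterable[EntitySpan], objects: Iterable[EntitySpan]
) -> list[tuple[EntitySpan, EntitySpan]]:
    """Full cross product of subject and object spans, minus identical pairs.

    Order is deterministic: by subject (h, t), then object (h, t).
    """
    subs = sorted(set(subjects), key=EntitySpan.key)
    objs = sorted(set(objects), key=EntitySpan.key)
    return [(s, o) for s in subs for o in objs if s.key() != o.key()]


def normalize_triplet(t: Triplet, mode: str = "string"):
    """Comparable key for strict matching.

    string mode compares whitespace-stripped surfaces (offset-insensitive);
    span mode compares exact token spans.
    """
    if mode == "string":
        return (t.s.surface.strip(), t.r, t.o.surface.strip())
    if mode == "span":
        return (t.s.key(), t.r, t.o.key())
    raise ValueError(f"unknown normalization mode {mode!r}")
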