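"""End-to-end orchestration of the bidirectional extraction pipeline.

Forward direction (entity pair -> relation): span detection at threshold
``a``, full pair enumeration, per-pair relation scores kept at threshold
``b``.  Reverse direction (relation -> entity pair): one prompt-conditioned
extraction per candidate relation at threshold ``c``.  The matching step then
keeps a candidate iff its relation score clears the matching threshold ``d``
(rule i, regardless of the reverse direction) or both of its arguments are
confirmed by the reverse direction for its own relation (rule ii); every
other candidate is deleted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .datamodel import CandidateTriplet, Document, Triplet, enumerate_pairs, normalize_triplet
from .duality import DLModel, DualitySets
from .er_span import ERModel
from .rc import RCModel

__all__ = ["Thresholds", "extract_so2r", "extract_r2so", "apply_matching", "predict"]


@dataclass(frozen=True)
class Thresholds:
    """The four inference thresholds: a (span detection), b (relation
    score floor), c (reverse-direction span detection), d (matching)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"threshold {name}={v} outside (0, 1]")


def extract_so2r(doc: Document, er: ERModel, rc: RCModel, a: float, b: float) -> list[CandidateTriplet]:
    """Forward direction: one candidate per (pair, relation) with score >= b."""
    subjects, objects = er.extract(doc, a)
    pairs = enumerate_pairs(subjects, objects)
    scores = rc.classify_pairs(doc, pairs)
    candidates: list[CandidateTriplet] = []
    for (s, o), row in zip(pairs, scores):
        for idx, rel in enumerate(rc.schema.labels):
            if row[idx] >= b:
                candidates.append(CandidateTriplet(Triplet(s, rel, o), float(row[idx])))
    return candidates


def extract_r2so(doc: Document, relations: Iterable[str], dl: DLModel, c: float) -> DualitySets:
    """Reverse direction: one prompt-conditioned extraction per distinct relation."""
    from .er_span import decode_spans

    duality = DualitySets()
    relations = sorted(set(relations))
    for rel in relations:
        if rel not in dl.schema:
            raise KeyError(f"relation {rel!r} not in schema")
    for rel, (ms, mo) in dl.score_many(doc, relations).items():
        duality.sets[rel] = (
            decode_spans(ms, c, dl.max_span_len, doc.tokens),
            decode_spans(mo, c, dl.max_span_len, doc.tokens),
        )
    return duality


def apply_matching(
    candidates: Iterable[CandidateTriplet],
    duality: DualitySets,
    d: float,
    pooled: bool = False,
) -> set[Triplet]:
    """Keep rule-passing candidates, de-duplicated by exact span identity.

    Rule (i): relation score >= d (kept regardless of the reverse direction).
    Rule (ii): subject in S' and object in O' for the candidate's own relation
    (or the pooled sets across relations when ``pooled``).
    """
    if not (0.0 < d <= 1.0):
        raise ValueError(f"matching threshold d={d} outside (0, 1]")
    kept: dict = {}
    pooled_sets = duality.pooled() if pooled else None
    for cand in candidates:
        t = cand.triplet
        if pooled:
            subs, objs = pooled_sets
        else:
            subs, objs = duality.subjects(t.r), duality.objects(t.r)
        rule_i = cand.gamma_rc >= d
        rule_ii = any(sp.key() == t.s.key() for sp in subs) and any(
            sp.key() == t.o.key() for sp in objs
        )
        if rule_i or rule_ii:
            kept.setdefault(normalize_triplet(t, "span"), t)
    return set(kept.values())


def predict(doc: Document, er: ERModel, rc: RCModel, dl: DLModel, th: Thresholds,
            pooled: bool = False) -> set[Triplet]:
    """Full bidirectional prediction for one document."""
    candidates = extract_so2r(doc, er, rc, th.a, th.b)
    duality = extract_r2so(doc, (c.triplet.r for c in candidates), dl, th.c)
    return apply_matching(candidates, duality, th.d, pooled=pooled)
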