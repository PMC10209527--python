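"""Strict triplet scoring, overlap/distance stratification and error taxonomy.

Strict scoring counts a predicted (s, r, o) correct only when all three
elements exactly match a gold triplet under the chosen normalization.
Stratified reports break performance down by overlap pattern (Normal / EPO /
SEO), number of triplets per sample (1, 2, 3, 4, >=5) and argument distance
(single- vs cross-sentence).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .datamodel import Document, Triplet, normalize_triplet

__all__ = [
    "EvalReport",
    "strict_prf",
    "classify_overlap",
    "classify_distance",
    "triplet_count_bin",
    "stratified_report",
    "error_breakdown",
    "SENTENCE_DELIMITERS",
]

SENTENCE_DELIMITERS = set("。！？!?.;；\n")

TRIPLET_BINS = ("1", "2", "3", "4", ">=5")


def triplet_count_bin(k: int) -> str:
    return str(k) if k <= 4 else ">=5"


def _prf(matched: int, n_pred: int, n_gold: int) -> tuple[float, float, float]:
    p = matched / n_pred if n_pred else 0.0
    r = matched / n_gold if n_gold else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f1


def strict_prf(
    pred: Mapping[str, Iterable[Triplet]],
    gold: Mapping[str, Iterable[Triplet]],
    mode: str = "string",
) -> tuple[float, float, float]:
    """Micro-averaged strict precision / recall / F1 over aligned documents."""
    if set(pred) != set(gold):
        raise ValueError("prediction and gold document ids differ")
    matched = n_pred = n_gold = 0
    for doc_id in gold:
        pk = {normalize_triplet(t, mode) for t in pred[doc_id]}
        gk = {normalize_triplet(t, mode) for t in gold[doc_id]}
        matched += len(pk & gk)
        n_pred += len(pk)
        n_gold += len(gk)
    return _prf(matched, n_pred, n_gold)


def classify_overlap(triplets: Iterable[Triplet], mode: str = "string") -> set[str]:
    """Overlap pattern(s) of one document's triplet set.

    EPO: two distinct triplets share the identical ordered (s, o) pair.
    SEO: two distinct triplets share exactly one argument entity.
    Normal: neither.  EPO and SEO can co-occur in one sample.
    """
    keys = sorted({normalize_triplet(t, mode) for t in triplets})
    patterns: set[str] = set()
    for i in range(len(keys)):
        si, ri, oi = keys[i]
        for j in range(i + 1, len(keys)):
            sj, rj, oj = keys[j]
            if si == sj and oi == oj:
                patterns.add("EPO")
            elif si == sj or oi == oj or si == oj or oi == sj:
                patterns.add("SEO")
    if not patterns:
        patterns.add("Normal")
    return patterns


def _sentence_index(doc: Document, token_idx: int) -> int:
    """Sentence ordinal of a token; spans use their start token's sentence."""
    idx = 0
    for i in range(token_idx):
        if doc.tokens[i] in SENTENCE_DELIMITERS:
            idx += 1
    return idx


def classify_distance(doc: Document, t: Triplet) -> str:
    s_sent = _sentence_index(doc, t.s.h)
    o_sent = _sentence_index(doc, t.o.h)
    return "single-sentence" if s_sent == o_sent else "cross-sentence"


def document_distance(doc: Document) -> str:
    """A document is cross-sentence iff any of its gold triplets is."""
    for t in doc.gold or ():
        if classify_distance(doc, t) == "cross-sentence":
            return "cross-sentence"
    return "single-sentence"


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    n_documents: int
    strata: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_documents": self.n_documents,
            "strata": self.strata,
            "errors": self.errors,
        }


def stratified_report(
    docs: Iterable[Document],
    pred: Mapping[str, Iterable[Triplet]],
    mode: str = "string",
) -> EvalReport:
    docs = list(docs)
    gold = {d.doc_id: set(d.gold or set()) for d in docs}
    pred = {d.doc_id: set(pred.get(d.doc_id, set())) for d in docs}
    p, r, f1 = strict_prf(pred, gold, mode)

    strata: dict[str, dict] = {"overlap": {}, "n_triplets": {}, "distance": {}}
    groups: dict[tuple[str, str], list[str]] = {}
    for d in docs:
        for pat in classify_overlap(d.gold or (), mode):
            groups.setdefault(("overlap", pat), []).append(d.doc_id)
        groups.setdefault(("n_triplets", triplet_count_bin(len(d.gold or ()))), []).append(d.doc_id)
        groups.setdefault(("distance", document_distance(d)), []).append(d.doc_id)
    for (kind, name), ids in sorted(groups.items()):
        sp = {i: pred[i] for i in ids}
        sg = {i: gold[i] for i in ids}
        pp, rr, ff = strict_prf(sp, sg, mode)
        strata[kind][name] = {"precision": pp, "recall": rr, "f1": ff, "n": len(ids)}

    errors = error_breakdown(pred, gold)
    return EvalReport(p, r, f1, len(docs), strata, dict(errors))


# --- five-way error taxonomy -------------------------------------------------

ERROR_CATEGORIES = (
    "entity_span_error_subject",
    "entity_span_error_object",
    "entity_type_error",
    "relation_error",
    "triplet_not_found",
    "triplet_redundancy",
)


def _overlaps(a: str, b: str) -> bool:
    a, b = a.strip(), b.strip()
    return a != b and (a in b or b in a)


def error_breakdown(
    pred: Mapping[str, Iterable[Triplet]],
    gold: Mapping[str, Iterable[Triplet]],
) -> Counter:
    """Assign every unmatched prediction/gold triplet one error category.

    Priority per unmatched prediction: span error (relation correct, exactly
    one argument overlaps-but-mismatches a gold argument), then relation error
    (both arguments match a gold pair, relation differs), else redundancy.
    Gold triplets explained by no prediction (even relaxed) count as not found.
    Entity-type errors are only scored when spans carry gold types; surface
    corpora score 0 there.
    """
    counts: Counter = Counter({c: 0 for c in ERROR_CATEGORIES})
    for doc_id in gold:
        gk = {normalize_triplet(t) for t in gold[doc_id]}
        pk = {normalize_triplet(t) for t in pred.get(doc_id, ())}
        unmatched_pred = pk - gk
        unmatched_gold = gk - pk
        explained_gold: set = set()
        for ps, pr, po in sorted(unmatched_pred):
            span_err = None
            rel_err = False
            for gs, gr, go in sorted(unmatched_gold):
                if pr == gr and go == po and _overlaps(ps, gs):
                    span_err = ("entity_span_error_subject", (gs, gr, go))
                    break
                if pr == gr and gs == ps and _overlaps(po, go):
                    span_err = ("entity_span_error_object", (gs, gr, go))
                    break
                if gs == ps and go == po and pr != gr:
                    rel_err = True
            if span_err is not None:
                counts[span_err[0]] += 1
                explained_gold.add(span_err[1])
            elif rel_err:
                counts["relation_error"] += 1
                explained_gold.update(
                    (gs, gr, go) for gs, gr, go in unmatched_gold if gs == ps and go == po
                )
            else:
                counts["triplet_redundancy"] += 1
        counts["triplet_not_found"] += len(unmatched_gold - explained_gold)
    return counts
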