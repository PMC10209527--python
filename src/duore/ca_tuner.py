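"""Two-stage grid search over the four inference thresholds.

Stage 1 fixes the forward-direction thresholds (a, b) at the grid point with
the highest candidate-triplet recall on the validation split, deliberately
letting many candidates through to the reverse-direction check.  Stage 2 then
fixes (c, d) at the point with the highest strict F1 of the full pipeline.
Ties are broken by higher precision, then by larger threshold values (the
more conservative setting).

The search caches raw model scores per document, so each grid point is a
cheap re-thresholding rather than a fresh forward pass; results are identical
to the naive stage-wise loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import Corpus, Triplet, enumerate_pairs, normalize_triplet
from .duality import DLModel, DualitySets
from .er_span import ERModel, decode_spans, sigmoid_np
from .pipeline import Thresholds
from .rc import RCModel

__all__ = ["GridSpec", "TuneReport", "tune"]


def _frange(lo: float, hi: float, step: float) -> tuple[float, ...]:
    vals = np.round(np.arange(lo, hi + 1e-9, step), 4)
    return tuple(float(v) for v in vals)


@dataclass(frozen=True)
class GridSpec:
    """Per-threshold candidate values, defaulting to the stated search ranges:
    a, c in (0.3, 0.6] step 0.05; b in [0.1, 0.5] step 0.05; d in [0.8, 1]
    step 0.02 plus the commonly probed 0.95."""

    a: Sequence[float] = _frange(0.35, 0.60, 0.05)
    b: Sequence[float] = _frange(0.10, 0.50, 0.05)
    c: Sequence[float] = _frange(0.35, 0.60, 0.05)
    d: Sequence[float] = tuple(sorted(set(_frange(0.80, 1.00, 0.02)) | {0.95}))

    def __post_init__(self):
        for name in "abcd":
            vals = getattr(self, name)
            if not len(vals):
                raise ValueError(f"empty grid for threshold {name}")
        _check_range("a", self.a, 0.3, 0.6, open_low=True)
        _check_range("b", self.b, 0.1, 0.5)
        _check_range("c", self.c, 0.3, 0.6, open_low=True)
        _check_range("d", self.d, 0.8, 1.0)


def _check_range(name, vals, lo, hi, open_low=False):
    for v in vals:
        ok = (v > lo if open_low else v >= lo) and v <= hi
        if not ok:
            raise ValueError(f"grid value {name}={v} outside the stated range")


@dataclass
class TuneReport:
    stage1: dict = field(default_factory=dict)  # (a, b) -> (recall, precision)
    stage2: dict = field(default_factory=dict)  # (c, d) -> (P, R, F1)
    best: Thresholds | None = None


class _DocCache:
    """Per-document raw scores enabling cheap re-thresholding: model forward
    passes run once per distinct (a) or relation, grid points only filter."""

    def __init__(self, doc, er: ERModel, rc: RCModel):
        self.doc = doc
        ms, mo = er.score(doc)
        self.sub_scores = ms
        self.obj_scores = mo
        self.er = er
        self.rc = rc
        self.pair_scores: dict = {}  # (s_key, o_key) -> per-relation probs
        self.pairs_at: dict = {}  # a -> list[(s, o)]
        self.dl_scores: dict = {}  # relation -> (ms, mo)

    def spans(self, a: float):
        n = min(self.doc.n, self.sub_scores.shape[0])
        toks = self.doc.tokens[:n]
        return (
            decode_spans(self.sub_scores, a, self.er.max_span_len, toks),
            decode_spans(self.obj_scores, a, self.er.max_span_len, toks),
        )

    def pairs(self, a: float):
        if a not in self.pairs_at:
            subs, objs = self.spans(a)
            pairs = enumerate_pairs(subs, objs)
            fresh = [p for p in pairs if (p[0].key(), p[1].key()) not in self.pair_scores]
            if fresh:
                scores = self.rc.classify_pairs(self.doc, fresh)
                for (s, o), row in zip(fresh, scores):
                    self.pair_scores[(s.key(), o.key())] = row
            self.pairs_at[a] = pairs
        return self.pairs_at[a]

    def candidates(self, a: float, b: float):
        out = []
        labels = self.rc.schema.labels
        for s, o in self.pairs(a):
            row = self.pair_scores[(s.key(), o.key())]
            for idx in np.flatnonzero(row >= b):
                out.append((Triplet(s, labels[idx], o), float(row[idx])))
        return out

    def duality(self, relations, dl: DLModel, c: float) -> DualitySets:
        relations = sorted(set(relations))
        missing = [r for r in relations if r not in self.dl_scores]
        if missing:
            self.dl_scores.update(dl.score_many(self.doc, missing))
        ds = DualitySets()
        for rel in relations:
            ms, mo = self.dl_scores[rel]
            ds.sets[rel] = (
                decode_spans(ms, c, dl.max_span_len, self.doc.tokens),
                decode_spans(mo, c, dl.max_span_len, self.doc.tokens),
            )
        return ds


def tune(er: ERModel, rc: RCModel, dl: DLModel, valid: Corpus,
         grid: GridSpec | None = None, mode: str = "string") -> tuple[Thresholds, TuneReport]:
    """Run the two-stage threshold search on a validation corpus with gold."""
    grid = grid or GridSpec()
    if len(valid) == 0:
        raise ValueError("empty validation corpus")
    gold = {d.doc_id: {normalize_triplet(t, mode) for t in d.gold or ()} for d in valid}
    n_gold = sum(len(g) for g in gold.values())
    if n_gold == 0:
        raise ValueError("validation corpus has no gold triplets")
    caches = [_DocCache(d, er, rc) for d in valid]
    report = TuneReport()

    # stage 1: candidate-triplet recall over (a, b); c and d are not consulted.
    # Per (doc, a) the distinct candidate keys are reduced to their maximum
    # relation score, so each b is a vectorized threshold count.
    b_floor = min(grid.b)
    best_ab = None
    best_key = None
    for a in grid.a:
        gold_max: list[np.ndarray] = []
        all_max: list[np.ndarray] = []
        for cache in caches:
            key_scores: dict = {}
            labels = rc.schema.labels
            for s, o in cache.pairs(a):
                row = cache.pair_scores[(s.key(), o.key())]
                for idx in np.flatnonzero(row >= b_floor):
                    k = (s.surface.strip(), labels[idx], o.surface.strip()) if mode == "string" else (
                        s.key(), labels[idx], o.key())
                    if row[idx] > key_scores.get(k, 0.0):
                        key_scores[k] = float(row[idx])
            g = gold[cache.doc.doc_id]
            gold_max.append(np.array([v for k, v in key_scores.items() if k in g]))
            all_max.append(np.array([v for v in key_scores.values()]))
        gvec = np.concatenate(gold_max) if gold_max else np.array([])
        avec = np.concatenate(all_max) if all_max else np.array([])
        for b in grid.b:
            matched = int((gvec >= b).sum())
            n_cand = int((avec >= b).sum())
            recall = matched / n_gold
            precision = matched / n_cand if n_cand else 0.0
            report.stage1[(a, b)] = (recall, precision)
            key = (recall, precision, a, b)
            if best_key is None or key > best_key:
                best_key, best_ab = key, (a, b)
    a_star, b_star = best_ab

    # stage 2: strict F1 of the full pipeline over (c, d) at fixed (a, b).
    # A candidate passes rule (i) iff gamma >= d and rule (ii) iff both of its
    # argument spans clear the reverse-direction probability at c, so each
    # de-duplicated key reduces to (max gamma, max min(span prob)).
    mg_parts, mp_parts, is_gold_parts = [], [], []
    for cache in caches:
        cands = cache.candidates(a_star, b_star)
        relations = sorted({t.r for t, _ in cands})
        missing = [r for r in relations if r not in cache.dl_scores]
        if missing:
            cache.dl_scores.update(dl.score_many(cache.doc, missing))
        per_key: dict = {}
        for t, gamma in cands:
            ms, mo = cache.dl_scores[t.r]
            ps = float(sigmoid_np(np.array([ms[t.s.h, t.s.t]]))[0]) if t.s.length <= dl.max_span_len else 0.0
            po = float(sigmoid_np(np.array([mo[t.o.h, t.o.t]]))[0]) if t.o.length <= dl.max_span_len else 0.0
            k = normalize_triplet(t, mode)
            mg, mp = per_key.get(k, (0.0, 0.0))
            per_key[k] = (max(mg, gamma), max(mp, min(ps, po)))
        g = gold[cache.doc.doc_id]
        for k, (mg, mp) in per_key.items():
            mg_parts.append(mg)
            mp_parts.append(mp)
            is_gold_parts.append(k in g)
    mg_vec = np.asarray(mg_parts)
    mp_vec = np.asarray(mp_parts)
    gold_vec = np.asarray(is_gold_parts, dtype=bool)

    best_cd = None
    best_key = None
    for c in grid.c:
        for d in grid.d:
            kept = (mg_vec >= d) | (mp_vec >= c)
            matched = int((kept & gold_vec).sum())
            n_pred = int(kept.sum())
            p = matched / n_pred if n_pred else 0.0
            r = matched / n_gold
            f1 = 2 * p * r / (p + r) if (p + r) else 0.0
            report.stage2[(c, d)] = (p, r, f1)
            key = (f1, p, c, d)
            if best_key is None or key > best_key:
                best_key, best_cd = key, (c, d)
    c_star, d_star = best_cd

    report.best = Thresholds(a_star, b_star, c_star, d_star)
    return report.best, report
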