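"""Readers and writers for the two public corpus dialects, plus statistics.

Supported dialects:

* a JSON Lines dialect where each record carries ``text`` and a ``spo_list``
  of predicate/subject/object annotations without character offsets (Chinese
  medical IE style) — spans are anchored by first-occurrence search;
* a TSV triad (abstracts, pre-annotated entities with character offsets, gold
  chemical–protein relations) in the BioCreative ChemProt style, where only
  the five evaluated CPR groups (3, 4, 5, 6, 9) become gold triplets.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .datamodel import Corpus, Document, EntitySpan, RelationSchema, SchemaEntry, Triplet
from . import evaluation

logger = logging.getLogger(__name__)

__all__ = ["read_cmeie", "read_chemprot", "write_jsonl", "corpus_stats", "merge_schemas", "StatReport"]


def merge_schemas(*corpora: Corpus) -> RelationSchema:
    """Union of inferred schemas (first definition of a label wins), sorted by
    label for determinism; use when per-split inference may miss rare
    relations."""
    entries: dict[str, SchemaEntry] = {}
    for corpus in corpora:
        for e in corpus.schema.entries:
            entries.setdefault(e.relation, e)
    return RelationSchema(entries[k] for k in sorted(entries))

EVALUATED_CPR_GROUPS = ("CPR:3", "CPR:4", "CPR:5", "CPR:6", "CPR:9")


def _char_tokens(text: str) -> list[str]:
    return list(text)


def _locate(text: str, needle: str, not_at: int | None = None) -> int:
    """First-occurrence anchor; `not_at` skips one forbidden start position."""
    start = text.find(needle)
    if start == not_at and start >= 0:
        start = text.find(needle, start + 1)
    return start


@dataclass
class _LocateFailure:
    predicate: str
    subject: str
    object: str
    reason: str


def read_cmeie(path: str | Path) -> Corpus:
    """Read a spo_list JSON Lines file into a Corpus.

    Spans are located by leftmost occurrence of the annotation string in
    ``text``; the schema is inferred from the observed (predicate,
    subject_type, object_type) combinations.  Records whose annotation string
    cannot be found keep the document but flag the triplet as a locate
    failure.
    """
    path = Path(path)
    documents: list[Document] = []
    schema_entries: dict[str, SchemaEntry] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                text = rec["text"]
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record ({exc})") from exc
            doc = Document(
                doc_id=str(rec.get("doc_id", f"{path.stem}-{lineno}")),
                text=text,
                tokens=_char_tokens(text),
                language=rec.get("language", "zh"),
                gold=set(),
            )
            for spo in rec.get("spo_list", ()):
                pred = spo["predicate"]
                subj = spo["subject"]
                obj = spo["object"]["@value"] if isinstance(spo.get("object"), dict) else spo["object"]
                stype = spo.get("subject_type", "")
                otype_field = spo.get("object_type", "")
                otype = otype_field.get("@value", "") if isinstance(otype_field, dict) else otype_field
                if pred not in schema_entries:
                    schema_entries[pred] = SchemaEntry(pred, pred, stype, otype)
                sh = _locate(text, subj)
                oh = _locate(text, obj)
                if sh >= 0 and oh >= 0 and (sh, len(subj)) == (oh, len(obj)):
                    # identical surfaces: re-anchor the object past the subject
                    oh = _locate(text, obj, not_at=sh)
                if sh < 0 or oh < 0 or (sh, len(subj)) == (oh, len(obj)):
                    doc.locate_failures.append(
                        _LocateFailure(pred, subj, obj, "annotation string not found in text")
                    )
                    continue
                doc.gold.add(
                    Triplet(
                        EntitySpan(sh, sh + len(subj) - 1, subj, stype or None),
                        pred,
                        EntitySpan(oh, oh + len(obj) - 1, obj, otype or None),
                    )
                )
            doc.validate()
            documents.append(doc)
    schema = RelationSchema(schema_entries.values())
    return Corpus(documents, schema, split=path.stem)


def read_chemprot(directory: str | Path, split: str) -> Corpus:
    """Read a BioCreative-style chemical–protein TSV triad.

    Expects ``<split>_abstracts.tsv`` (id, title, abstract),
    ``<split>_entities.tsv`` (id, term, type, start, end, text) and
    ``<split>_gold_standard.tsv`` (id, CPR group, Arg1:term, Arg2:term).
    Document text is title + tab + abstract; offsets are validated against
    the entity text column and mismatches are fatal, naming the term id.
    """
    directory = Path(directory)

    def rows(name: str):
        p = directory / f"{split}_{name}.tsv"
        with p.open(encoding="utf-8", newline="") as fh:
            yield from csv.reader(fh, delimiter="\t")

    texts: dict[str, str] = {}
    for row in rows("abstracts"):
        doc_id, title, abstract = row[0], row[1], row[2]
        texts[doc_id] = f"{title}\t{abstract}"

    entities: dict[tuple[str, str], EntitySpan] = {}
    for row in rows("entities"):
        doc_id, term_id, etype, start, end, surface = row[:6]
        if doc_id not in texts:
            raise ValueError(f"entity {term_id} references unknown abstract {doc_id}")
        start, end = int(start), int(end)
        sliced = texts[doc_id][start:end]
        if sliced != surface:
            raise ValueError(
                f"term {term_id} in {doc_id}: offset slice {sliced!r} != entity text {surface!r}"
            )
        # character offsets are half-open; token spans inclusive (char tokens)
        entities[(doc_id, term_id)] = EntitySpan(start, end - 1, surface, etype)

    gold: dict[str, set[Triplet]] = {d: set() for d in texts}
    dropped = 0
    for row in rows("gold_standard"):
        doc_id, group, arg1, arg2 = row[0], row[1], row[2], row[3]
        if group not in EVALUATED_CPR_GROUPS:
            dropped += 1
            continue
        t1 = arg1.split(":", 1)[1]
        t2 = arg2.split(":", 1)[1]
        try:
            s = entities[(doc_id, t1)]
            o = entities[(doc_id, t2)]
        except KeyError as exc:
            raise ValueError(f"relation in {doc_id} references unknown term {exc.args[0]}") from exc
        gold[doc_id].add(Triplet(s, group, o))
    if dropped:
        logger.info("dropped %d relations outside the evaluated CPR groups", dropped)

    schema = RelationSchema(
        SchemaEntry(g, g, "CHEMICAL", "GENE") for g in EVALUATED_CPR_GROUPS
    )
    documents = [
        Document(doc_id, text, _char_tokens(text), language="en", gold=gold[doc_id])
        for doc_id, text in texts.items()
    ]
    for doc in documents:
        doc.validate()
    return Corpus(documents, schema, split=split)


def write_jsonl(corpus: Corpus, path: str | Path) -> None:
    """Serialize a corpus in the spo_list JSON Lines dialect (UTF-8)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus:
            spo_list = []
            for t in sorted(doc.gold or (), key=lambda t: (t.s.key(), t.r, t.o.key())):
                spo_list.append(
                    {
                        "predicate": t.r,
                        "subject": t.s.surface,
                        "subject_type": t.s.etype or corpus.schema[t.r].stype,
                        "object": {"@value": t.o.surface},
                        "object_type": {"@value": t.o.etype or corpus.schema[t.r].otype},
                    }
                )
            for lf in doc.locate_failures:
                spo_list.append(
                    {
                        "predicate": lf.predicate,
                        "subject": lf.subject,
                        "subject_type": "",
                        "object": {"@value": lf.object},
                        "object_type": {"@value": ""},
                    }
                )
            rec = {"doc_id": doc.doc_id, "language": doc.language, "text": doc.text, "spo_list": spo_list}
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


@dataclass
class StatReport:
    """Corpus statistics: sample counts, per-type entity and relation counts,
    overlap-pattern counts, triplet-count histogram and distance counts."""

    split: str
    n_samples: int
    n_relations: int
    entities_by_type: Counter = field(default_factory=Counter)
    relations_by_type: Counter = field(default_factory=Counter)
    overlap_patterns: Counter = field(default_factory=Counter)
    triplet_histogram: Counter = field(default_factory=Counter)
    distance: Counter = field(default_factory=Counter)
    n_locate_failures: int = 0

    def as_dict(self) -> dict:
        return {
            "split": self.split,
            "n_samples": self.n_samples,
            "n_relations": self.n_relations,
            "entities_by_type": dict(self.entities_by_type),
            "relations_by_type": dict(self.relations_by_type),
            "overlap_patterns": dict(self.overlap_patterns),
            "triplet_histogram": dict(self.triplet_histogram),
            "distance": dict(self.distance),
            "n_locate_failures": self.n_locate_failures,
        }


def corpus_stats(corpus: Corpus) -> StatReport:
    """Compute per-split statistics; a sample can count under both EPO and SEO."""
    rep = StatReport(corpus.split, len(corpus), corpus.schema.l)
    for doc in corpus:
        triplets = doc.gold or set()
        spans = {sp.key(): sp for t in triplets for sp in (t.s, t.o)}
        for sp in spans.values():
            etype = sp.etype or "UNTYPED"
            if etype.startswith("GENE"):
                etype = "Protein"  # GENE-Y / GENE-N reported together
            rep.entities_by_type[etype] += 1
        for t in triplets:
            rep.relations_by_type[t.r] += 1
        for pat in evaluation.classify_overlap(triplets):
            rep.overlap_patterns[pat] += 1
        rep.triplet_histogram[evaluation.triplet_count_bin(len(triplets))] += 1
        rep.distance[evaluation.document_distance(doc)] += 1
        rep.n_locate_failures += len(doc.locate_failures)
    return rep
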