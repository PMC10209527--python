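"""Corpus readers/writers: field mapping, validation, round trips, stats."""

import json

import pytest

from duore.corpus_io import corpus_stats, read_chemprot, read_cmeie, write_jsonl
from duore.datamodel import normalize_triplet
from duore.synthetic import SyntheticConfig, generate_corpus, generate_schema


def _write_jsonl(path, records):
    path.write_text("\n".join(json.dumps(r, ensure_ascii=False) for r in records) + "\n",
                    encoding="utf-8")


class TestReadCmeie:
    def test_direct_field_mapping(self, tmp_path):
        p = tmp_path / "train.jsonl"
        _write_jsonl(p, [{
            "text": "AB治C",
            "spo_list": [{
                "predicate": "治疗", "subject": "AB", "subject_type": "药物",
                "object": {"@value": "C"}, "object_type": {"@value": "疾病"},
            }],
        }])
        corpus = read_cmeie(p)
        assert len(corpus) == 1
        (doc,) = corpus.documents
        (t,) = doc.gold
        assert (t.s.h, t.s.t, t.s.surface) == (0, 1, "AB")
        assert t.r == "治疗" and t.o.surface == "C"
        assert corpus.schema.l == 1

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.jsonl"
        p.write_text("")
        assert len(read_cmeie(p)) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.jsonl"
        p.write_text('{"text": "ok", "spo_list": []}\nnot json\n')
        with pytest.raises(ValueError, match=":2"):
            read_cmeie(p)

    def test_unlocatable_annotation_is_flagged_not_fatal(self, tmp_path):
        p = tmp_path / "miss.jsonl"
        _write_jsonl(p, [{
            "text": "plain text",
            "spo_list": [{"predicate": "r", "subject": "absent",
                          "object": {"@value": "text"}}],
        }])
        corpus = read_cmeie(p)
        (doc,) = corpus.documents
        assert doc.gold == set()
        assert len(doc.locate_failures) == 1

    def test_first_occurrence_anchoring(self, tmp_path):
        p = tmp_path / "dup.jsonl"
        _write_jsonl(p, [{
            "text": "xy z xy",
            "spo_list": [{"predicate": "r", "subject": "xy", "object": {"@value": "z"}}],
        }])
        (doc,) = read_cmeie(p).documents
        (t,) = doc.gold
        assert t.s.key() == (0, 1)  # leftmost occurrence


class TestRoundTrip:
    def test_generator_corpus_round_trips(self, tmp_path):
        cfg = SyntheticConfig(n_docs=25, seed=11)
        corpus = generate_corpus(cfg, generate_schema(cfg), "train")
        p = tmp_path / "rt.jsonl"
        write_jsonl(corpus, p)
        back = read_cmeie(p)
        assert len(back) == len(corpus)
        for a, b in zip(corpus, back):
            assert a.text == b.text
            assert {normalize_triplet(t) for t in a.gold} == {normalize_triplet(t) for t in b.gold}
            assert not b.locate_failures

    def test_empty_corpus_writes_empty_file(self, tmp_path):
        cfg = SyntheticConfig(n_docs=1, seed=3)
        corpus = generate_corpus(cfg, generate_schema(cfg), "train")
        corpus.documents = []
        p = tmp_path / "empty.jsonl"
        write_jsonl(corpus, p)
        assert p.read_text() == ""


CHEMPROT_ABSTRACT = "Aspirin inhibits COX2\tThe drug aspirin strongly inhibits COX2 enzymes."


def _chemprot_dir(tmp_path, entity_rows=None, gold_rows=None):
    d = tmp_path / "chemprot"
    d.mkdir()
    (d / "training_abstracts.tsv").write_text("10001\t" + CHEMPROT_ABSTRACT + "\n")
    entity_rows = entity_rows or [
        ("10001", "T1", "CHEMICAL", 0, 7, "Aspirin"),
        ("10001", "T2", "GENE-Y", 17, 21, "COX2"),
    ]
    (d / "training_entities.tsv").write_text(
        "\n".join("\t".join(map(str, r)) for r in entity_rows) + "\n"
    )
    gold_rows = gold_rows if gold_rows is not None else [
        ("10001", "CPR:4", "Arg1:T1", "Arg2:T2"),
    ]
    (d / "training_gold_standard.tsv").write_text(
        "\n".join("\t".join(r) for r in gold_rows) + ("\n" if gold_rows else "")
    )
    return d


class TestReadChemprot:
    def test_toy_directory(self, tmp_path):
        corpus = read_chemprot(_chemprot_dir(tmp_path), "training")
        (doc,) = corpus.documents
        assert doc.text.startswith("Aspirin inhibits COX2\t")
        (t,) = doc.gold
        assert t.r == "CPR:4"
        assert t.s.surface == "Aspirin" and t.s.etype == "CHEMICAL"
        assert t.o.surface == "COX2" and t.o.etype == "GENE-Y"

    def test_offset_text_mismatch_names_term(self, tmp_path):
        d = _chemprot_dir(
            tmp_path,
            entity_rows=[("10001", "T9", "CHEMICAL", 0, 7, "Ibuprofen")],
            gold_rows=[],
        )
        with pytest.raises(ValueError, match="T9"):
            read_chemprot(d, "training")

    def test_unknown_term_in_relation(self, tmp_path):
        d = _chemprot_dir(tmp_path, gold_rows=[("10001", "CPR:4", "Arg1:T1", "Arg2:T99")])
        with pytest.raises(ValueError, match="T99"):
            read_chemprot(d, "training")

    def test_unevaluated_groups_dropped(self, tmp_path):
        d = _chemprot_dir(tmp_path, gold_rows=[
            ("10001", "CPR:4", "Arg1:T1", "Arg2:T2"),
            ("10001", "CPR:10", "Arg1:T1", "Arg2:T2"),
        ])
        corpus = read_chemprot(d, "training")
        assert {t.r for t in corpus.documents[0].gold} == {"CPR:4"}

    def test_typed_span_invariant(self, tmp_path):
        corpus = read_chemprot(_chemprot_dir(tmp_path), "training")
        for doc in corpus:
            for t in doc.gold:
                types = {t.s.etype, t.o.etype}
                assert "CHEMICAL" in types
                assert any(x.startswith("GENE") for x in types)


class TestCorpusStats:
    def test_histogram_counts(self):
        cfg = SyntheticConfig(n_docs=40, seed=5)
        corpus = generate_corpus(cfg, generate_schema(cfg), "valid")
        rep = corpus_stats(corpus)
        assert sum(rep.triplet_histogram.values()) == len(corpus)
        assert rep.n_samples == 40
        by_bin = {b: sum(1 for d in corpus if min(len(d.gold), 5) == (5 if b == ">=5" else int(b)))
                  for b in rep.triplet_histogram}
        assert rep.triplet_histogram == by_bin

    def test_chemprot_protein_grouping(self, tmp_path):
        corpus = read_chemprot(_chemprot_dir(tmp_path), "training")
        rep = corpus_stats(corpus)
        assert rep.entities_by_type == {"CHEMICAL": 1, "Protein": 1}
        assert rep.relations_by_type == {"CPR:4": 1}
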