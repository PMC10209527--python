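"""Loss oracles, overfit-capacity checks and training determinism."""

import numpy as np
import pytest

from duore.datamodel import Corpus, RelationSchema, SchemaEntry, Triplet
from duore.encoding import EncoderConfig
from duore.nn import Tensor
from duore.training import TrainConfig, binary_span_loss, fit_module, rdrop_loss

from conftest import make_doc, span


class TestBinarySpanLoss:
    def test_confident_positive_is_zero(self):
        loss = binary_span_loss(Tensor(np.array([40.0])), np.array([1.0]))
        assert float(loss.data) < 1e-9

    def test_uncertain_positive_is_ln2(self):
        loss = binary_span_loss(Tensor(np.array([0.0])), np.array([1.0]))
        assert np.isclose(float(loss.data), np.log(2.0), atol=1e-6)

    def test_matches_direct_recomputation(self, rng):
        x = rng.standard_normal(50).astype(np.float64)
        y = (rng.random(50) > 0.7).astype(np.float64)
        got = float(binary_span_loss(Tensor(x), y).data)
        p = 1.0 / (1.0 + np.exp(-x))
        want = float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))
        assert np.isclose(got, want, atol=1e-9)

    def test_weighted_mean_restricts_units(self, rng):
        x = rng.standard_normal(20).astype(np.float64)
        y = np.zeros(20)
        w = np.zeros(20)
        w[:5] = 1.0
        got = float(binary_span_loss(Tensor(x), y, w).data)
        want = float(binary_span_loss(Tensor(x[:5]), y[:5]).data)
        assert np.isclose(got, want, atol=1e-9)

    def test_nonnegative_and_zero_only_at_labels(self, rng):
        x = rng.standard_normal(30)
        y = (rng.random(30) > 0.5).astype(np.float64)
        assert float(binary_span_loss(Tensor(x), y).data) > 0
        perfect = np.where(y > 0.5, 40.0, -40.0)
        assert float(binary_span_loss(Tensor(perfect), y).data) < 1e-9


class TestRdropLoss:
    def test_identical_passes_reduce_to_plain_loss(self, rng):
        x = rng.standard_normal(30).astype(np.float64)
        y = (rng.random(30) > 0.5).astype(np.float64)
        got = float(rdrop_loss(Tensor(x), Tensor(x.copy()), y, alpha=1.0).data)
        want = float(binary_span_loss(Tensor(x), y).data)
        assert np.isclose(got, want, atol=1e-9)

    def test_alpha_zero_is_mean_of_losses(self, rng):
        x1 = rng.standard_normal(30).astype(np.float64)
        x2 = rng.standard_normal(30).astype(np.float64)
        y = (rng.random(30) > 0.5).astype(np.float64)
        got = float(rdrop_loss(Tensor(x1), Tensor(x2), y, alpha=0.0).data)
        want = 0.5 * (
            float(binary_span_loss(Tensor(x1), y).data) + float(binary_span_loss(Tensor(x2), y).data)
        )
        assert np.isclose(got, want, atol=1e-9)

    def test_matches_hand_computed_formula(self, rng):
        x1 = rng.standard_normal(20).astype(np.float64)
        x2 = rng.standard_normal(20).astype(np.float64)
        y = (rng.random(20) > 0.5).astype(np.float64)
        alpha = 0.7
        got = float(rdrop_loss(Tensor(x1), Tensor(x2), y, alpha).data)
        p1, p2 = 1 / (1 + np.exp(-x1)), 1 / (1 + np.exp(-x2))

        def bce(p):
            return np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p)))

        kl12 = p1 * np.log(p1 / p2) + (1 - p1) * np.log((1 - p1) / (1 - p2))
        kl21 = p2 * np.log(p2 / p1) + (1 - p2) * np.log((1 - p2) / (1 - p1))
        want = 0.5 * (bce(p1) + bce(p2)) + alpha * np.mean(0.5 * (kl12 + kl21))
        assert np.isclose(got, want, atol=1e-9)


# --- tiny fixture corpora ----------------------------------------------------

SCHEMA = RelationSchema([
    SchemaEntry("r1", "T", "bab", "gag"),
    SchemaEntry("r2", "V", "bab", "gag"),
])


def _one_doc_corpus(text, triplet_specs, split="train"):
    doc = make_doc(text, doc_id=f"{split}-0")
    doc.gold = {
        Triplet(span(doc, *s), r, span(doc, *o)) for s, r, o in triplet_specs
    }
    doc.validate()
    return Corpus([doc], SCHEMA, split)


@pytest.fixture(scope="module")
def single_doc():
    # "bamo T gigu" : bamo --r1--> gigu
    return _one_doc_corpus("bamo T gigu .", [((0, 3), "r1", (7, 10))])


@pytest.fixture(scope="module")
def overfit_cfg():
    # max_valid_docs=0 selects by training loss, the right criterion for a
    # memorisation-capacity check
    return TrainConfig(batch_size=4, lr=5e-3, epochs=300, weight_decay=0.0,
                       dropout={"er": 0.0, "rc": 0.0, "dl": 0.0}, rdrop_alpha=0.0,
                       max_valid_docs=0, seed=3)


ENC = EncoderConfig(layers=2, d=32, heads=2, d_ffn=64, dropout=0.0, max_len=64)


class TestOverfitCapacity:
    def test_er_recovers_gold_spans(self, single_doc, overfit_cfg):
        er, rep = fit_module("er", single_doc, single_doc, overfit_cfg, enc_cfg=ENC)
        assert rep.losses[-1] < 0.01
        doc = single_doc.documents[0]
        subs, objs = er.extract(doc, 0.5)
        assert {s.key() for s in subs} == {(0, 3)}
        assert {o.key() for o in objs} == {(7, 10)}

    def test_er_recovers_nested_spans(self, overfit_cfg):
        # object "gigu" sits inside subject "bagigup": both must surface
        corpus = _one_doc_corpus("bagigup T .", [((0, 6), "r1", (2, 5))])
        er, _ = fit_module("er", corpus, corpus, overfit_cfg, enc_cfg=ENC)
        doc = corpus.documents[0]
        subs, objs = er.extract(doc, 0.5)
        assert (0, 6) in {s.key() for s in subs}
        assert (2, 5) in {o.key() for o in objs}

    def test_rc_overfits_single_pair(self, single_doc, overfit_cfg):
        from duore.rc import insert_markers

        rc, _ = fit_module("rc", single_doc, single_doc, overfit_cfg, enc_cfg=ENC)
        doc = single_doc.documents[0]
        scores = rc.classify_pair(insert_markers(doc, span(doc, 0, 3), span(doc, 7, 10)))
        assert scores[SCHEMA.index("r1")] > 0.9
        assert scores[SCHEMA.index("r2")] < 0.1

    def test_rc_multilabel_epo_pair(self, overfit_cfg):
        from duore.rc import insert_markers

        corpus = _one_doc_corpus(
            "bamo T gigu . bamo V gigu .",
            [((0, 3), "r1", (7, 10)), ((14, 17), "r2", (21, 24))],
        )
        # same surface pair under both relations: multi-label head must
        # support two scores above threshold at once
        rc, _ = fit_module("rc", corpus, corpus, overfit_cfg, enc_cfg=ENC)
        doc = corpus.documents[0]
        s1 = rc.classify_pair(insert_markers(doc, span(doc, 0, 3), span(doc, 7, 10)))
        s2 = rc.classify_pair(insert_markers(doc, span(doc, 14, 17), span(doc, 21, 24)))
        assert s1[SCHEMA.index("r1")] > 0.5
        assert s2[SCHEMA.index("r2")] > 0.5

    def test_dl_extracts_relation_conditioned_sets(self, overfit_cfg):
        corpus = _one_doc_corpus(
            "bamo T gigu . bedi V gogu .",
            [((0, 3), "r1", (7, 10)), ((14, 17), "r2", (21, 24))],
        )
        dl, _ = fit_module("dl", corpus, corpus, overfit_cfg, enc_cfg=ENC)
        doc = corpus.documents[0]
        s1, o1 = dl.dual_extract(doc, "r1", 0.5)
        s2, o2 = dl.dual_extract(doc, "r2", 0.5)
        assert {s.key() for s in s1} == {(0, 3)}
        assert {o.key() for o in o1} == {(7, 10)}
        assert {s.key() for s in s2} == {(14, 17)}
        assert {o.key() for o in o2} == {(21, 24)}


class TestFitContracts:
    def test_same_seed_identical_traces(self, single_doc):
        cfg = TrainConfig(batch_size=2, lr=1e-3, epochs=3, seed=11)
        _, rep1 = fit_module("er", single_doc, single_doc, cfg, enc_cfg=ENC)
        _, rep2 = fit_module("er", single_doc, single_doc, cfg, enc_cfg=ENC)
        assert rep1.losses == rep2.losses
        assert rep1.metrics == rep2.metrics

    def test_selection_returns_argmax_checkpoint(self, single_doc):
        cfg = TrainConfig(batch_size=2, lr=5e-3, epochs=4, seed=1)
        _, rep = fit_module("er", single_doc, single_doc, cfg, enc_cfg=ENC)
        assert rep.best_metric == max(rep.metrics)
        # among ties, the latest checkpoint is kept
        assert rep.best_epoch == max(i for i, m in enumerate(rep.metrics) if m == rep.best_metric)

    def test_empty_corpus_rejected(self, single_doc):
        empty = Corpus([], SCHEMA, "train")
        with pytest.raises(ValueError):
            fit_module("er", empty, single_doc, TrainConfig(epochs=1))

    def test_schema_mismatch_rejected(self, single_doc):
        other = Corpus([], RelationSchema([SchemaEntry("x", "X", "a", "b")]), "valid")
        with pytest.raises(ValueError):
            fit_module("er", single_doc, other, TrainConfig(epochs=1))

    def test_unknown_kind_rejected(self, single_doc):
        with pytest.raises(ValueError):
            fit_module("joint", single_doc, single_doc, TrainConfig(epochs=1))
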