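"""Strict scoring, overlap/distance classification and error taxonomy."""

import numpy as np
import pytest

from duore.datamodel import EntitySpan, Triplet
from duore.evaluation import (
    classify_distance,
    classify_overlap,
    error_breakdown,
    strict_prf,
    stratified_report,
    triplet_count_bin,
)

from conftest import make_doc, span


def _t(s, r, o, base=0):
    return Triplet(
        EntitySpan(base, base + max(len(s) - 1, 0), s),
        r,
        EntitySpan(base + 20, base + 20 + max(len(o) - 1, 0), o),
    )


class TestStrictPRF:
    def test_perfect_prediction(self):
        gold = {"d": {_t("A", "r1", "B")}}
        assert strict_prf(gold, gold) == (1.0, 1.0, 1.0)

    def test_partial_overlap_counts(self):
        gold = {"d": {_t("A", "r1", "B"), _t("C", "r1", "D")}}
        pred = {"d": {_t("A", "r1", "B"), _t("X", "r1", "Y"), _t("P", "r2", "Q")}}
        p, r, f1 = strict_prf(pred, gold)
        assert (p, r) == (1 / 3, 1 / 2)
        assert np.isclose(f1, 0.4)

    def test_empty_prediction_convention(self):
        gold = {"d": {_t("A", "r1", "B")}}
        assert strict_prf({"d": set()}, gold) == (0.0, 0.0, 0.0)

    def test_document_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            strict_prf({"a": set()}, {"b": set()})

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_set_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed)

        def random_sets():
            out = {}
            for d in range(4):
                out[f"doc{d}"] = {
                    _t(f"e{rng.integers(4)}", f"r{rng.integers(3)}", f"e{rng.integers(4)}", base=0)
                    for _ in range(rng.integers(0, 5))
                }
            return out

        pred, gold = random_sets(), random_sets()
        p, r, f1 = strict_prf(pred, gold)
        # independent oracle: brute-force key-set intersection
        def keys(ts):
            return {(t.s.surface.strip(), t.r, t.o.surface.strip()) for t in ts}

        matched = sum(len(keys(pred[d]) & keys(gold[d])) for d in gold)
        np_, ng = sum(len(keys(pred[d])) for d in gold), sum(len(keys(gold[d])) for d in gold)
        po = matched / np_ if np_ else 0.0
        ro = matched / ng if ng else 0.0
        fo = 2 * po * ro / (po + ro) if po + ro else 0.0
        assert np.allclose((p, r, f1), (po, ro, fo))


class TestClassifyOverlap:
    def test_entity_pair_overlap(self):
        assert classify_overlap({_t("A", "r1", "B"), _t("A", "r2", "B")}) == {"EPO"}

    def test_single_entity_overlap(self):
        assert classify_overlap({_t("A", "r1", "B"), _t("A", "r2", "C")}) == {"SEO"}

    def test_single_triplet_is_normal(self):
        assert classify_overlap({_t("A", "r1", "B")}) == {"Normal"}

    def test_epo_and_seo_can_cooccur(self):
        got = classify_overlap({_t("A", "r1", "B"), _t("A", "r2", "B"), _t("A", "r1", "C")})
        assert got == {"EPO", "SEO"}

    def test_normal_iff_no_overlap(self):
        for ts in [
            {_t("A", "r1", "B"), _t("C", "r1", "D")},
            {_t("A", "r1", "B")},
            set(),
        ]:
            got = classify_overlap(ts)
            assert ("Normal" in got) == ("EPO" not in got and "SEO" not in got)

    def test_shared_argument_across_positions_is_seo(self):
        # object of one triplet equals subject of another
        assert classify_overlap({_t("A", "r1", "B"), _t("B", "r1", "C")}) == {"SEO"}


class TestClassifyDistance:
    def test_one_sentence_document(self):
        doc = make_doc("ab cd ef")
        t = Triplet(span(doc, 0, 1), "r", span(doc, 6, 7))
        assert classify_distance(doc, t) == "single-sentence"

    def test_arguments_in_different_sentences(self):
        doc = make_doc("ab . cd .")
        t = Triplet(span(doc, 0, 1), "r", span(doc, 5, 6))
        assert classify_distance(doc, t) == "cross-sentence"

    def test_straddling_span_uses_start_token_sentence(self):
        doc = make_doc("ab . cd .")
        t = Triplet(span(doc, 0, 5), "r", span(doc, 0, 1))
        # subject starts in sentence 0 despite covering the delimiter
        assert classify_distance(doc, t) == "single-sentence"

    def test_count_bins(self):
        assert [triplet_count_bin(k) for k in (1, 2, 3, 4, 5, 9)] == ["1", "2", "3", "4", ">=5", ">=5"]


class TestErrorBreakdown:
    def test_relation_error(self):
        counts = error_breakdown({"d": {_t("A", "r2", "B")}}, {"d": {_t("A", "r1", "B")}})
        assert counts["relation_error"] == 1
        assert counts["triplet_not_found"] == 0

    def test_missing_prediction_is_not_found(self):
        counts = error_breakdown({"d": set()}, {"d": {_t("A", "r1", "B")}})
        assert counts["triplet_not_found"] == 1

    def test_object_span_error_on_substring(self):
        counts = error_breakdown({"d": {_t("A", "r1", "Bx")}}, {"d": {_t("A", "r1", "Bxy")}})
        assert counts["entity_span_error_object"] == 1
        assert counts["triplet_not_found"] == 0

    def test_subject_span_error_on_substring(self):
        counts = error_breakdown({"d": {_t("Ayz", "r1", "B")}}, {"d": {_t("Az" + "yz", "r1", "B")}})
        assert counts["entity_span_error_subject"] + counts["triplet_redundancy"] == 1

    def test_pure_redundancy(self):
        counts = error_breakdown(
            {"d": {_t("A", "r1", "B"), _t("X", "r1", "Y")}}, {"d": {_t("A", "r1", "B")}}
        )
        assert counts["triplet_redundancy"] == 1

    def test_hand_classified_fixture(self):
        gold = {
            "d": {
                _t("aspirin", "treats", "headache"),
                _t("aspirin", "prevents", "stroke"),
                _t("statin", "treats", "lipidemia"),
            }
        }
        pred = {
            "d": {
                _t("aspirin", "treats", "headache"),   # correct
                _t("aspirin", "cures", "stroke"),      # relation error
                _t("statin", "treats", "lipid"),       # object span error
                _t("zinc", "treats", "cold"),          # redundancy
            }
        }
        counts = error_breakdown(pred, gold)
        assert counts["relation_error"] == 1
        assert counts["entity_span_error_object"] == 1
        assert counts["triplet_redundancy"] == 1
        assert counts["triplet_not_found"] == 0


class TestStratifiedReport:
    def test_report_covers_strata_and_micro_scores(self):
        d1 = make_doc("ab cd ef", doc_id="d1")
        d1.gold = {Triplet(span(d1, 0, 1), "r1", span(d1, 3, 4))}
        d2 = make_doc("gh ij kl", doc_id="d2")
        d2.gold = {
            Triplet(span(d2, 0, 1), "r1", span(d2, 3, 4)),
            Triplet(span(d2, 0, 1), "r2", span(d2, 3, 4)),
        }
        pred = {"d1": set(d1.gold), "d2": set()}
        rep = stratified_report([d1, d2], pred)
        assert np.isclose(rep.recall, 1 / 3)
        assert np.isclose(rep.precision, 1.0)
        assert set(rep.strata["overlap"]) == {"Normal", "EPO"}
        assert rep.strata["n_triplets"]["1"]["f1"] == 1.0
        assert rep.strata["n_triplets"]["2"]["f1"] == 0.0
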