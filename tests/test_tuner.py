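"""Two-stage threshold search vs an independent stage-wise brute force."""

import numpy as np
import pytest

from duore.ca_tuner import GridSpec, tune
from duore.datamodel import normalize_triplet
from duore.encoding import EncoderConfig
from duore.pipeline import Thresholds, extract_so2r, predict
from duore.synthetic import SyntheticConfig, generate_corpus, generate_schema
from duore.training import build_tokenizer


@pytest.fixture(scope="module")
def tiny_setup():
    # lightly trained models over a tiny corpus: gold spans score high, the
    # rest spread below, so the grid points carve out distinct candidate sets
    from duore.training import TrainConfig, fit_module

    cfg = SyntheticConfig(n_docs=4, seed=13, entity_len_range=(2, 3),
                          triplet_count_weights=(0.6, 0.4, 0, 0, 0),
                          p_epo=0.2, p_seo=0.3, p_nested=0.0, p_cross_sentence=0.2)
    schema = generate_schema(cfg)
    valid = generate_corpus(cfg, schema, "valid")
    tok = build_tokenizer(valid)
    enc = EncoderConfig(layers=1, d=16, heads=2, d_ffn=16, dropout=0.0, max_len=64)
    tcfg = TrainConfig(batch_size=4, lr=5e-3, epochs=12, weight_decay=0.0,
                       dropout={"er": 0.0, "rc": 0.0, "dl": 0.0}, rdrop_alpha=0.0,
                       max_valid_docs=0, seed=99)
    er, _ = fit_module("er", valid, valid, tcfg, tok, enc)
    rc, _ = fit_module("rc", valid, valid, tcfg, tok, enc)
    dl, _ = fit_module("dl", valid, valid, tcfg, tok, enc)
    er.max_span_len = 6
    dl.max_span_len = 6
    return er, rc, dl, valid


GRID = GridSpec(a=(0.4, 0.5, 0.6), b=(0.1, 0.3, 0.5), c=(0.4, 0.5, 0.6), d=(0.8, 0.9, 1.0))


def brute_force(er, rc, dl, valid, grid):
    """Naive stage-wise loops through the public pipeline API."""
    gold = {d.doc_id: {normalize_triplet(t) for t in d.gold} for d in valid}
    n_gold = sum(len(g) for g in gold.values())

    best1, best1_key = None, None
    for a in grid.a:
        for b in grid.b:
            matched = n_cand = 0
            for doc in valid:
                keys = {normalize_triplet(c.triplet) for c in extract_so2r(doc, er, rc, a, b)}
                matched += len(keys & gold[doc.doc_id])
                n_cand += len(keys)
            rec = matched / n_gold
            prec = matched / n_cand if n_cand else 0.0
            key = (rec, prec, a, b)
            if best1_key is None or key > best1_key:
                best1_key, best1 = key, (a, b)
    a_star, b_star = best1

    best2, best2_key = None, None
    for c in grid.c:
        for d in grid.d:
            matched = n_pred = 0
            for doc in valid:
                th = Thresholds(a_star, b_star, c, d)
                keys = {normalize_triplet(t) for t in predict(doc, er, rc, dl, th)}
                matched += len(keys & gold[doc.doc_id])
                n_pred += len(keys)
            p = matched / n_pred if n_pred else 0.0
            r = matched / n_gold
            f1 = 2 * p * r / (p + r) if p + r else 0.0
            key = (f1, p, c, d)
            if best2_key is None or key > best2_key:
                best2_key, best2 = key, (c, d)
    return Thresholds(a_star, b_star, *best2)


class TestTune:
    def test_singleton_grid_returns_that_point(self, tiny_setup):
        er, rc, dl, valid = tiny_setup
        grid = GridSpec(a=(0.45,), b=(0.25,), c=(0.55,), d=(0.9,))
        th, _ = tune(er, rc, dl, valid, grid)
        assert th == Thresholds(0.45, 0.25, 0.55, 0.9)

    def test_matches_stagewise_brute_force(self, tiny_setup):
        er, rc, dl, valid = tiny_setup
        th, report = tune(er, rc, dl, valid, GRID)
        want = brute_force(er, rc, dl, valid, GRID)
        assert th == want
        # stage-2 winner maximises F1 over the (c, d) grid
        best_f1 = max(v[2] for v in report.stage2.values())
        assert report.stage2[(th.c, th.d)][2] == best_f1

    def test_stage1_ignores_c_and_d(self, tiny_setup):
        er, rc, dl, valid = tiny_setup
        th1, r1 = tune(er, rc, dl, valid, GRID)
        shuffled = GridSpec(a=GRID.a, b=GRID.b, c=(0.6, 0.4), d=(1.0, 0.8))
        th2, r2 = tune(er, rc, dl, valid, shuffled)
        assert (th1.a, th1.b) == (th2.a, th2.b)
        assert r1.stage1 == r2.stage1

    def test_result_lies_inside_grid(self, tiny_setup):
        er, rc, dl, valid = tiny_setup
        th, _ = tune(er, rc, dl, valid, GRID)
        assert th.a in GRID.a and th.b in GRID.b and th.c in GRID.c and th.d in GRID.d

    def test_report_tables_cover_grid(self, tiny_setup):
        er, rc, dl, valid = tiny_setup
        _, report = tune(er, rc, dl, valid, GRID)
        assert set(report.stage1) == {(a, b) for a in GRID.a for b in GRID.b}
        assert set(report.stage2) == {(c, d) for c in GRID.c for d in GRID.d}

    def test_empty_validation_rejected(self, tiny_setup):
        er, rc, dl, valid = tiny_setup
        from duore.datamodel import Corpus

        with pytest.raises(ValueError):
            tune(er, rc, dl, Corpus([], valid.schema, "valid"), GRID)


class TestGridSpec:
    def test_defaults_lie_in_stated_ranges(self):
        g = GridSpec()
        assert all(0.3 < a <= 0.6 for a in g.a)
        assert all(0.1 <= b <= 0.5 for b in g.b)
        assert all(0.3 < c <= 0.6 for c in g.c)
        assert all(0.8 <= d <= 1.0 for d in g.d)
        assert {0.8, 0.9, 0.95, 0.98} <= set(g.d)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(a=(0.3,))
        with pytest.raises(ValueError):
            GridSpec(d=(0.7,))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(b=())
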