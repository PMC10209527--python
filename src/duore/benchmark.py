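"""The synthetic end-to-end benchmark: generate, train, tune, evaluate.

This is the package's reference experiment.  It generates a seeded synthetic
corpus with the structural profile the framework targets (ten relations with
a zipf_s = 1.2 long tail, entity-pair overlap in 10% and single-entity
overlap in 30% of multi-fact samples, 20% cross-sentence arguments), trains
the three modules with the co-adaptive strategy on a compact 2-layer, d=64
encoder, tunes the four inference thresholds on the validation split and
scores strict triplet F1 on the held-out test split.

The corpus seed is part of the benchmark definition (seed 7); the run seed
only drives model initialisation and training stochasticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .ca_tuner import GridSpec, tune
from .datamodel import Corpus
from .encoding import EncoderConfig
from .evaluation import strict_prf
from .pipeline import Thresholds, extract_so2r
from .synthetic import SyntheticConfig, generate_corpus, generate_schema
from .training import TrainConfig, build_tokenizer, fit_module

__all__ = ["BenchmarkSpec", "BenchmarkResult", "make_corpora", "robustness_spec", "run_benchmark"]

#: corpus-generation conditions of the benchmark (fixed, incl. corpus seed)
BENCHMARK_SYNTH = SyntheticConfig(
    n_relations=10,
    zipf_s=1.2,
    p_epo=0.1,
    p_seo=0.3,
    p_cross_sentence=0.2,
    seed=7,
)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Problem sizes and model hyperparameters of the reference experiment.

    The split sizes keep one full run (train all three modules + threshold
    tuning + test scoring) around ten CPU-minutes; the structural corpus
    parameters above are never varied.
    """

    n_train: int = 700
    n_valid: int = 150
    n_test: int = 150
    enc: EncoderConfig = EncoderConfig(layers=2, d=64, heads=4, d_ffn=128, max_len=256)
    train: TrainConfig = TrainConfig(batch_size=24, lr=2e-3, max_valid_docs=25,
                                     dl_negative_samples=2,
                                     rc_negative_ratio=2.5, rc_corrupt_ratio=2.0)
    #: per-module epoch counts and learning-rate schedules: span-detection
    #: precision keeps improving long after recall saturates, so the span
    #: module trains longest; the reverse module uses a cosine-decayed run
    epochs: tuple = (("er", 55), ("rc", 10), ("dl", 18))
    schedules: tuple = (("er", "constant"), ("rc", "constant"), ("dl", "cosine"))
    grid: GridSpec = GridSpec()
    #: when set, skip threshold tuning and evaluate at these fixed values
    fixed_thresholds: Optional[Thresholds] = None


#: reduced problem size for multi-seed robustness checks (direction of the
#: precision gain, not absolute performance)
ROBUSTNESS_SPEC_KWARGS = dict(
    n_train=150,
    n_valid=30,
    n_test=60,
    epochs=(("er", 30), ("rc", 8), ("dl", 10)),
    # direction-of-effect check: fixed mid-range thresholds for every seed
    # (same forward thresholds on both sides of the comparison), checkpoint
    # selection by training loss, no per-seed grid search
    fixed_thresholds=Thresholds(a=0.5, b=0.3, c=0.5, d=0.98),
    train=TrainConfig(batch_size=24, lr=2e-3, max_valid_docs=0,
                      dl_negative_samples=2,
                      rc_negative_ratio=2.5, rc_corrupt_ratio=2.0),
)


def robustness_spec() -> "BenchmarkSpec":
    return BenchmarkSpec(**ROBUSTNESS_SPEC_KWARGS)


@dataclass
class BenchmarkResult:
    seed: int
    thresholds: Thresholds
    test_f1: float
    test_precision: float
    test_recall: float
    forward_only_precision: float
    forward_only_recall: float
    forward_only_f1: float
    reports: dict = field(default_factory=dict)


def make_corpora(spec: BenchmarkSpec) -> tuple[Corpus, Corpus, Corpus]:
    schema = generate_schema(BENCHMARK_SYNTH)
    train = generate_corpus(replace(BENCHMARK_SYNTH, n_docs=spec.n_train), schema, "train")
    valid = generate_corpus(replace(BENCHMARK_SYNTH, n_docs=spec.n_valid), schema, "valid")
    test = generate_corpus(replace(BENCHMARK_SYNTH, n_docs=spec.n_test), schema, "test")
    return train, valid, test


def run_benchmark(seed: int, spec: Optional[BenchmarkSpec] = None,
                  corpora: Optional[tuple[Corpus, Corpus, Corpus]] = None) -> BenchmarkResult:
    """One full co-adaptive run at a given training seed."""
    spec = spec or BenchmarkSpec()
    train, valid, test = corpora if corpora is not None else make_corpora(spec)
    tokenizer = build_tokenizer(train, valid, test)
    cfg = replace(spec.train, seed=int(seed) % (2**31))
    epochs = dict(spec.epochs)
    schedules = dict(spec.schedules)

    def module_cfg(kind):
        return replace(cfg, epochs=epochs[kind], lr_schedule=schedules[kind])

    er, er_rep = fit_module("er", train, valid, module_cfg("er"), tokenizer, spec.enc)
    rc, rc_rep = fit_module("rc", train, valid, module_cfg("rc"), tokenizer, spec.enc)
    dl, dl_rep = fit_module("dl", train, valid, module_cfg("dl"), tokenizer, spec.enc)

    if spec.fixed_thresholds is not None:
        th, tune_rep = spec.fixed_thresholds, None
    else:
        th, tune_rep = tune(er, rc, dl, valid, spec.grid)

    from .pipeline import apply_matching, extract_r2so

    # the forward direction is computed once per document and reused for both
    # the full pipeline score and the forward-only ablation
    pred, fwd_pred = {}, {}
    for doc in test:
        cands = extract_so2r(doc, er, rc, th.a, th.b)
        duality = extract_r2so(doc, (c.triplet.r for c in cands), dl, th.c)
        pred[doc.doc_id] = apply_matching(cands, duality, th.d)
        fwd_pred[doc.doc_id] = {c.triplet for c in cands}
    gold = {doc.doc_id: set(doc.gold or ()) for doc in test}
    p, r, f1 = strict_prf(pred, gold)
    fp, fr, ff1 = strict_prf(fwd_pred, gold)

    return BenchmarkResult(
        seed=seed,
        thresholds=th,
        test_f1=f1,
        test_precision=p,
        test_recall=r,
        forward_only_precision=fp,
        forward_only_recall=fr,
        forward_only_f1=ff1,
        reports={"er": er_rep, "rc": rc_rep, "dl": dl_rep, "tune": tune_rep},
    )
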