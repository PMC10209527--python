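"""Losses, consistency regularisation and module training.

Training follows a co-adaptive strategy: the forward-direction modules
(span detection and relation classification) select checkpoints by recall, so
that few correct triplets are lost before the reverse-direction check, while
the reverse (prompt-conditioned) module selects by span-level F1 and trains
with an R-Drop consistency term between two stochastic forward passes.

All heads are trained with full binary cross-entropy under the logistic
scoring function, i.e. both planted positives and the exhaustive negatives of
each score matrix contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .datamodel import Corpus, Document, EntitySpan, enumerate_pairs
from .duality import DLModel
from .encoding import CLS, CharTokenizer, Encoder, EncoderConfig, SEP, pad_batch
from .er_span import ERModel, decode_spans
from .nn import Adam, Tensor
from .nn.losses import bce_with_logits, bernoulli_sym_kl
from .rc import RCModel, insert_markers

__all__ = ["TrainConfig", "FitReport", "binary_span_loss", "rdrop_loss", "fit_module", "build_tokenizer"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 24
    epochs: int = 10
    lr: float = 4e-5
    weight_decay: float = 0.01
    dropout: dict = field(default_factory=lambda: {"er": 0.3, "rc": 0.4, "dl": 0.3})
    rdrop_alpha: float = 1.0
    selection: dict = field(default_factory=lambda: {"er": "recall", "rc": "recall", "dl": "f1"})
    rc_negative_ratio: float = 1.0
    rc_corrupt_ratio: float = 1.0
    dl_negative_samples: int = 1
    span_pos_weight: float = 30.0
    lr_schedule: str = "constant"  # or "cosine"
    max_valid_docs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.lr <= 0:
            raise ValueError("batch size, epochs and learning rate must be positive")
        for k, v in self.dropout.items():
            if not (0.0 <= v < 1.0):
                raise ValueError(f"dropout[{k}]={v} outside [0, 1)")


# --- losses ------------------------------------------------------------------


def binary_span_loss(scores: Tensor, labels: np.ndarray, weights: Optional[np.ndarray] = None) -> Tensor:
    """Mean binary cross-entropy of logistic(score) against 0/1 labels.

    `weights` (same shape) restricts the mean to valid units, e.g. the
    h <= t cells of a span matrix inside the unpadded region.
    """
    return bce_with_logits(scores, labels, weights)


def rdrop_loss(scores1: Tensor, scores2: Tensor, labels: np.ndarray, alpha: float,
               weights: Optional[np.ndarray] = None) -> Tensor:
    """Mean of the two cross-entropies plus alpha x symmetric KL between the
    two per-unit Bernoulli distributions (average of both directions)."""
    bce = (bce_with_logits(scores1, labels, weights) + bce_with_logits(scores2, labels, weights)) * 0.5
    return bce + alpha * bernoulli_sym_kl(scores1, scores2, weights)


# --- data preparation --------------------------------------------------------


def build_tokenizer(*corpora: Corpus) -> CharTokenizer:
    texts = []
    for c in corpora:
        for doc in c:
            texts.append(doc.text)
        for e in c.schema.entries:
            texts.extend([e.rtype, e.stype, e.otype])
    return CharTokenizer.from_texts(texts)


def _span_label_matrix(n_padded: int, n_content: int, spans, max_span_len: int):
    """0/1 label matrix plus the valid-cell weight mask for one sequence."""
    y = np.zeros((n_padded, n_padded), dtype=np.float32)
    for sp in spans:
        if sp.t < n_content:
            y[sp.h, sp.t] = 1.0
    h = np.arange(n_padded)[:, None]
    t = np.arange(n_padded)[None, :]
    w = ((t >= h) & (t - h + 1 <= max_span_len) & (t < n_content)).astype(np.float32)
    return y, w


def _gold_spans(doc: Document) -> tuple[set[EntitySpan], set[EntitySpan]]:
    subs = {t.s for t in doc.gold or ()}
    objs = {t.o for t in doc.gold or ()}
    return subs, objs


@dataclass
class FitReport:
    kind: str
    metric_name: str
    losses: list = field(default_factory=list)
    metrics: list = field(default_factory=list)
    best_epoch: int = -1
    best_metric: float = -1.0


def _batches(n: int, batch_size: int, rng: np.random.Generator,
             lengths: Optional[list] = None):
    """Shuffled mini-batches; with `lengths`, batches group similar lengths
    (random jitter inside buckets) to avoid quadratic padding waste."""
    if lengths is None:
        order = rng.permutation(n)
    else:
        jitter = rng.random(n)
        order = np.asarray(sorted(range(n), key=lambda i: (lengths[i], jitter[i])))
    batches = [order[i : i + batch_size] for i in range(0, n, batch_size)]
    for k in rng.permutation(len(batches)):
        yield batches[k]


# --- per-module trainers -----------------------------------------------------


def _pos_weighted(w: np.ndarray, y: np.ndarray, pos_weight: float) -> np.ndarray:
    """Upweight the sparse positive cells of a span matrix; the weighted mean
    keeps per-unit binary cross-entropy semantics while preventing the
    all-negative collapse of a heavily imbalanced matrix."""
    if pos_weight == 1.0:
        return w
    return w * (1.0 + (pos_weight - 1.0) * y)


def _er_loss(model: ERModel, docs: list[Document], dropout: float,
             rng: np.random.Generator, pos_weight: float = 1.0) -> Tensor:
    tok = model.encoder.tokenizer
    seqs = [tok.to_ids(tok.tokenize(d.text, wrap=True, max_len=model.encoder.cfg.max_len)) for d in docs]
    ids, mask = pad_batch(seqs, tok.pad_id)
    vectors = model.encoder.net(ids, mask=mask, dropout=dropout, rng=rng)
    content = vectors[:, 1:, :]  # drop [CLS]; content token i at row i
    n_pad = content.shape[1]
    ys, yo, ws = [], [], []
    for d in docs:
        n_content = min(d.n, model.encoder.cfg.max_len - 2)
        subs, objs = _gold_spans(d)
        y_s, w = _span_label_matrix(n_pad, n_content, subs, model.max_span_len)
        y_o, _ = _span_label_matrix(n_pad, n_content, objs, model.max_span_len)
        ys.append(y_s)
        yo.append(y_o)
        ws.append(w)
    ys, yo, ws = np.stack(ys), np.stack(yo), np.stack(ws)
    scores_s = model.subject_head(content)
    scores_o = model.object_head(content)
    return binary_span_loss(scores_s, ys, _pos_weighted(ws, ys, pos_weight)) + binary_span_loss(
        scores_o, yo, _pos_weighted(ws, yo, pos_weight)
    )


def _er_metric(model: ERModel, docs: list[Document]) -> float:
    """Span recall at the permissive inference floor a=0.3."""
    found = total = 0
    for d in docs:
        subs, objs = model.extract(d, 0.3)
        gs, go = _gold_spans(d)
        found += len({s.key() for s in subs} & {s.key() for s in gs})
        found += len({o.key() for o in objs} & {o.key() for o in go})
        total += len(gs) + len(go)
    return found / total if total else 0.0


def _rc_instances(corpus: Corpus, cfg: TrainConfig, rng: np.random.Generator):
    instances = []  # (doc, s, o, label_vec)
    l = corpus.schema.l
    for doc in corpus:
        gold = doc.gold or set()
        if not gold:
            continue
        by_pair: dict = {}
        for t in gold:
            by_pair.setdefault((t.s, t.o), np.zeros(l, dtype=np.float32))[corpus.schema.index(t.r)] = 1.0
        for (s, o), y in sorted(by_pair.items(), key=lambda kv: (kv[0][0].key(), kv[0][1].key())):
            instances.append((doc, s, o, y))
        subs, objs = _gold_spans(doc)
        negatives = [
            (s, o)
            for s, o in enumerate_pairs(subs | objs, subs | objs)
            if (s, o) not in by_pair
        ]
        n_neg = min(len(negatives), max(1, int(round(cfg.rc_negative_ratio * len(by_pair)))))
        if negatives and n_neg:
            for idx in rng.choice(len(negatives), size=n_neg, replace=False):
                s, o = negatives[idx]
                instances.append((doc, s, o, np.zeros(l, dtype=np.float32)))
        # boundary-corrupted negatives: a gold pair with one argument trimmed
        # or extended by one token, labeled no-relation — the classifier must
        # reject the near-miss spans a high-recall span detector proposes
        n_corrupt = int(round(cfg.rc_corrupt_ratio * len(by_pair)))
        pairs = sorted(by_pair, key=lambda p: (p[0].key(), p[1].key()))
        for _ in range(n_corrupt):
            s, o = pairs[int(rng.integers(len(pairs)))]
            which = int(rng.integers(2))
            span = (s, o)[which]
            h, t = span.h, span.t
            moves = [(h + 1, t), (h, t - 1), (h - 1, t), (h, t + 1)]
            valid = [(hh, tt) for hh, tt in moves if 0 <= hh <= tt < doc.n]
            if not valid:
                continue
            hh, tt = valid[int(rng.integers(len(valid)))]
            corrupted = EntitySpan(hh, tt, "".join(doc.tokens[hh : tt + 1]))
            pair = (corrupted, o) if which == 0 else (s, corrupted)
            if pair in by_pair or pair[0].key() == pair[1].key():
                continue
            instances.append((doc, pair[0], pair[1], np.zeros(l, dtype=np.float32)))
    return instances


def _rc_loss(model: RCModel, batch, dropout: float, rng: np.random.Generator) -> Tensor:
    tok = model.encoder.tokenizer
    seqs, s_pos, o_pos, ys = [], [], [], []
    from .encoding import S_OPEN, O_OPEN

    for doc, s, o, y in batch:
        marked = insert_markers(doc, s, o)
        tokens = [CLS, *marked.tokens, SEP]
        seqs.append(tok.to_ids(tokens))
        s_pos.append(marked.marker_positions[S_OPEN] + 1)
        o_pos.append(marked.marker_positions[O_OPEN] + 1)
        ys.append(y)
    ids, mask = pad_batch(seqs, tok.pad_id)
    vectors = model.encoder.net(ids, mask=mask, dropout=dropout, rng=rng)
    rows = np.arange(len(batch))
    v_s = vectors[rows, np.asarray(s_pos)]
    v_o = vectors[rows, np.asarray(o_pos)]
    logits = model.classifier(v_s, v_o)
    return binary_span_loss(logits, np.stack(ys))


def _rc_metric(model: RCModel, docs: list[Document]) -> float:
    """Gold-pair relation recall at the permissive floor b=0.1."""
    hit = total = 0
    for doc in docs:
        triplets = sorted(doc.gold or (), key=lambda t: (t.s.key(), t.r, t.o.key()))
        if not triplets:
            continue
        scores = model.classify_pairs(doc, [(t.s, t.o) for t in triplets])
        for t, row in zip(triplets, scores):
            hit += bool(row[model.schema.index(t.r)] >= 0.1)
            total += 1
    return hit / total if total else 0.0


def _dl_instances(corpus: Corpus, cfg: TrainConfig, rng: np.random.Generator):
    instances = []  # (doc, relation, subject_spans, object_spans)
    labels = corpus.schema.labels
    for doc in corpus:
        present: dict = {}
        for t in sorted(doc.gold or (), key=lambda t: (t.r, t.s.key(), t.o.key())):
            subs, objs = present.setdefault(t.r, (set(), set()))
            subs.add(t.s)
            objs.add(t.o)
        for rel, (subs, objs) in sorted(present.items()):
            instances.append((doc, rel, subs, objs))
        absent = [r for r in labels if r not in present]
        if absent and cfg.dl_negative_samples:
            n = min(len(absent), cfg.dl_negative_samples)
            for idx in rng.choice(len(absent), size=n, replace=False):
                instances.append((doc, absent[idx], set(), set()))
    return instances


def _dl_loss(model: DLModel, batch, dropout: float, rng: np.random.Generator,
             alpha: float, pos_weight: float = 1.0) -> Tensor:
    tok = model.encoder.tokenizer
    seqs, offsets = [], []
    for doc, rel, _, _ in batch:
        tokens, offset = model.assemble(doc, rel)
        seqs.append(tok.to_ids(tokens))
        offsets.append(offset)
    if len(set(offsets)) != 1:
        raise ValueError("batch must share one prompt offset; group instances by offset")
    offset = offsets[0]
    ids, mask = pad_batch(seqs, tok.pad_id)

    def forward():
        vectors = model.encoder.net(ids, mask=mask, dropout=dropout, rng=rng)
        text = vectors[:, offset:, :]
        return model.subject_head(text), model.object_head(text)

    n_pad = ids.shape[1] - offset
    ys, yo, ws = [], [], []
    for (doc, rel, subs, objs), seq in zip(batch, seqs):
        n_content = len(seq) - offset - 1  # drop trailing [SEP]
        y_s, w = _span_label_matrix(n_pad, n_content, subs, model.max_span_len)
        y_o, _ = _span_label_matrix(n_pad, n_content, objs, model.max_span_len)
        ys.append(y_s)
        yo.append(y_o)
        ws.append(w)
    ys, yo, ws = np.stack(ys), np.stack(yo), np.stack(ws)
    ws_s = _pos_weighted(ws, ys, pos_weight)
    ws_o = _pos_weighted(ws, yo, pos_weight)

    if alpha > 0 and dropout > 0:
        s1, o1 = forward()
        s2, o2 = forward()
        return rdrop_loss(s1, s2, ys, alpha, ws_s) + rdrop_loss(o1, o2, yo, alpha, ws_o)
    s1, o1 = forward()
    return binary_span_loss(s1, ys, ws_s) + binary_span_loss(o1, yo, ws_o)


def _dl_metric(model: DLModel, docs: list[Document]) -> float:
    """Micro span-level F1 of the reverse direction at threshold 0.5."""
    tp = n_pred = n_gold = 0
    for doc in docs:
        present: dict = {}
        for t in doc.gold or ():
            subs, objs = present.setdefault(t.r, (set(), set()))
            subs.add(t.s.key())
            objs.add(t.o.key())
        scored = model.score_many(doc, list(present)) if present else {}
        for rel, (subs, objs) in sorted(present.items()):
            ms, mo = scored[rel]
            ps = decode_spans(ms, 0.5, model.max_span_len)
            po = decode_spans(mo, 0.5, model.max_span_len)
            pk_s = {p.key() for p in ps}
            pk_o = {p.key() for p in po}
            tp += len(pk_s & subs) + len(pk_o & objs)
            n_pred += len(pk_s) + len(pk_o)
            n_gold += len(subs) + len(objs)
    p = tp / n_pred if n_pred else 0.0
    r = tp / n_gold if n_gold else 0.0
    return 2 * p * r / (p + r) if (p + r) else 0.0


# --- orchestration -----------------------------------------------------------


def fit_module(
    kind: str,
    train: Corpus,
    valid: Corpus,
    cfg: TrainConfig,
    tokenizer: Optional[CharTokenizer] = None,
    enc_cfg: Optional[EncoderConfig] = None,
    template_id: int = 5,
):
    """Train one module and return (model, FitReport).

    Checkpoint selection: span recall for `er`, gold-pair relation recall for
    `rc` (both at permissive floors, keeping the forward direction
    high-recall) and reverse-direction span F1 for `dl`.  Two runs with the
    same config and seed produce identical metric traces.
    """
    if kind not in ("er", "rc", "dl"):
        raise ValueError(f"unknown module kind {kind!r}")
    if len(train) == 0:
        raise ValueError("empty training corpus")
    if train.schema != valid.schema:
        raise ValueError("train and valid must share a schema")

    enc_cfg = enc_cfg or EncoderConfig()
    enc_cfg = replace(enc_cfg, dropout=cfg.dropout.get(kind, enc_cfg.dropout))
    tokenizer = tokenizer or build_tokenizer(train, valid)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, {"er": 1, "rc": 2, "dl": 3}[kind]]))

    if kind == "er":
        model = ERModel.build(tokenizer, enc_cfg, rng)
        instances = list(train.documents)
        loss_fn = lambda batch: _er_loss(model, batch, enc_cfg.dropout, rng, cfg.span_pos_weight)
        metric_fn = lambda docs: _er_metric(model, docs)
    elif kind == "rc":
        model = RCModel.build(tokenizer, enc_cfg, train.schema, rng)
        instances = _rc_instances(train, cfg, rng)
        loss_fn = lambda batch: _rc_loss(model, batch, enc_cfg.dropout, rng)
        metric_fn = lambda docs: _rc_metric(model, docs)
    else:
        model = DLModel.build(tokenizer, enc_cfg, train.schema, rng, template_id=template_id)
        instances = _dl_instances(train, cfg, rng)
        loss_fn = lambda batch: _dl_loss(model, batch, enc_cfg.dropout, rng, cfg.rdrop_alpha,
                                         cfg.span_pos_weight)
        metric_fn = lambda docs: _dl_metric(model, docs)

    selection = cfg.selection.get(kind, "recall")
    report = FitReport(kind, selection)
    params = model.parameters()
    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    valid_docs = valid.documents[: cfg.max_valid_docs]
    best_state = None

    if kind == "dl":
        from .duality import build_prompt

        offsets = [len(build_prompt(template_id, train.schema[rel]).tokens) + 2 for _, rel, _, _ in instances]
        doc_lens = [inst[0].n for inst in instances]

        def make_batches():
            # batches must share a prompt offset; within an offset group,
            # bucket by text length
            groups: dict = {}
            for i, off in enumerate(offsets):
                groups.setdefault(off, []).append(i)
            batches = []
            for off in sorted(groups):
                idxs = groups[off]
                jitter = rng.random(len(idxs))
                order = sorted(range(len(idxs)), key=lambda j: (doc_lens[idxs[j]], jitter[j]))
                for j in range(0, len(order), cfg.batch_size):
                    batches.append(np.asarray([idxs[q] for q in order[j : j + cfg.batch_size]]))
            return [batches[k] for k in rng.permutation(len(batches))]

    else:
        if kind == "er":
            lengths = [d.n for d in instances]
        else:
            lengths = [inst[0].n for inst in instances]

        def make_batches():
            return list(_batches(len(instances), cfg.batch_size, rng, lengths))

    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.lr * 0.5 * (1.0 + math.cos(math.pi * epoch / cfg.epochs))
        epoch_losses = []
        for idxs in make_batches():
            batch = [instances[i] for i in idxs]
            opt.zero_grad()
            loss = loss_fn(batch)
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        report.losses.append(float(np.mean(epoch_losses)))
        metric = metric_fn(valid_docs) if valid_docs else -float(np.mean(epoch_losses))
        report.metrics.append(metric)
        # ties go to the later (longer-trained) checkpoint: recall saturates
        # early while boundary precision keeps improving
        if metric >= report.best_metric:
            report.best_metric = metric
            report.best_epoch = epoch
            best_state = {k: v.data.copy() for k, v in params.items()}

    if best_state is not None:
        for k, p in params.items():
            p.data[...] = best_state[k]
    return model, report
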