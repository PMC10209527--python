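# duore

Bidirectional (duality-aware) extraction of (subject, relation, object)
triplets from biomedical text, with rule-based matching of the two
directions and co-adaptive threshold tuning.

## The problem

Biomedical relation extraction turns sentences like *"Rifampicin reduces
annual morbidity in contacts of leprosy patients"* into structured facts
— (rifampicin, prevention, leprosy) — for knowledge-base construction and
EHR mining. Pipeline systems (find entities, then classify each pair)
lose precision to error propagation: a spurious entity pair, once
proposed, is easily assigned a spurious relation. `duore` counters this
with a *duality* check: next to the forward direction

    text → entity spans (S, O) → relation scores per pair   (SO2R)

it runs the reverse direction

    text + relation prompt → argument sets (S', O')          (R2SO)

and keeps a candidate triplet (s, r, o) only if its relation score γ
clears a matching threshold d, **or** both s ∈ S′(r) and o ∈ O′(r) — the
reverse extraction confirms the forward one. Four inference thresholds
(span detection a, relation floor b, reverse detection c, matching d) are
tuned in two stages on validation data: (a, b) by candidate recall (let
candidates through to be checked), then (c, d) by strict F1 (set the
filtering strength).

The span detector scores every token span [h, t] with a rotary-position
bilinear form M[h,t] = (W₁v_h+b₁)ᵀ R_hᵀ R_t (W₂v_t+b₂) — a global
span matrix that allows nested entities. The relation classifier reads
the pair through entity markers [s]…[/s], [o]…[/o]; the reverse module is
conditioned by a prompt built from the relation's type names,
`[/s1]{rtype}[/s2]{stype}[/s3]{otype}`. Evaluation is strict micro
P/R/F1 — a prediction counts only when all three elements match gold —
with stratified reports over overlap patterns (Normal / entity-pair
overlap / single-entity overlap), triplet counts and argument distance,
plus a five-way error taxonomy.

Everything runs on a compact built-in transformer (2 layers, d = 64, on
a numpy autodiff core), trained end-to-end on corpora from the package's
seeded synthetic generator, which reproduces the structural phenomena of
the public benchmarks: long-tailed relation frequencies, EPO/SEO
overlaps, nested mentions, multi-triplet samples and cross-sentence
arguments. Readers for the two public corpus dialects (spo_list JSON
Lines; the chemical–protein TSV triad with CPR:3/4/5/6/9 gold groups)
are included.

## Worked example

The reference benchmark (700/150/150 synthetic documents, ten relations;
about ten minutes on one CPU) trains the three modules, tunes the four
thresholds on validation and scores the held-out test split:

```python
from duore.benchmark import BenchmarkSpec, run_benchmark

res = run_benchmark(seed=7, spec=BenchmarkSpec())
print(f"tuned thresholds a={res.thresholds.a} b={res.thresholds.b} "
      f"c={res.thresholds.c} d={res.thresholds.d}")
print(f"full pipeline  P={res.test_precision:.3f} R={res.test_recall:.3f} "
      f"F1={res.test_f1:.3f}")
print(f"forward only   P={res.forward_only_precision:.3f} "
      f"R={res.forward_only_recall:.3f} F1={res.forward_only_f1:.3f}")
```

```
tuned thresholds a=0.4 b=0.1 c=0.45 d=1.0
full pipeline  P=0.853 R=0.905 F1=0.878
forward only   P=0.672 R=0.912 F1=0.774
```

The tuner deliberately fixes permissive forward thresholds (a = 0.4,
b = 0.1): the forward direction alone then recalls 91% of gold triplets
but only 67% of what it proposes is correct. The reverse + matching
stage deletes the candidates it cannot confirm, giving up less than one
point of recall for an eighteen-point precision gain. That division of
labour — a high-recall forward pass, a self-checking reverse pass — is
the point of the architecture.

The same run is available from the shell:

    duore generate --seed 7 --n-docs 200 --out-dir corpus/
    duore train --module all --train corpus/train.jsonl --valid corpus/valid.jsonl \
          --checkpoint-dir ckpt/
    duore tune --valid corpus/valid.jsonl --checkpoint-dir ckpt/ --out thresholds.yaml
    duore predict --input corpus/test.jsonl --checkpoint-dir ckpt/ \
          --thresholds-file thresholds.yaml --out pred.jsonl
    duore evaluate --pred pred.jsonl --gold corpus/test.jsonl --strata

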