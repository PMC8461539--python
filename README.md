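# riskmine

**Veracity classification and causal risk-perception mining for short
health-related social-media messages.**

Public discussion of vaccines on social media mixes accurate information
with misinformation, and much of the misinformation is argued *causally*:
"the vaccine causes X".  `riskmine` is a pipeline for researchers in health
infodemiology who want to (a) classify short messages as containing true or
false vaccine information and (b) extract and rank the *candidate effect
phrases* — the risk perceptions — that messages causally attribute to a
vaccine, then validate them against a curated risk-perception lexicon.

## The method

1. **Normalize** — rule-based lexical normalization (lower-casing, URL
   removal, `NUMBER`/`MENTION`/`RT` special tokens, contraction expansion,
   punctuation stripping).
2. **Classify** — a parallel-convolution text CNN (kernel widths 3/4/5,
   max pooling, dense + softmax; Adam, cross-entropy) labels each message
   true/false information; BiLSTM, SVM and Naive-Bayes baselines share the
   interface.  Downstream mining keeps only predictions with confidence
   ≥ 0.998 (configurable).
3. **Extract** — messages containing a causal cue ("causes", "leads to",
   "due to", ...) yield candidate pairs: noun phrases left of the cue form
   the cause phrase *c*, phrases to the right the effect phrase *e*.
4. **Model** — over the pair sets *C* and *E* with vocabularies *V_c*,
   *V_e* (stopwords and hapax terms removed), a Laplace-smoothed joint
   table gives, for terms *w_c* ∈ *V_c*, *w_e* ∈ *V_e*,

   ```
   PMI(w_c, w_e)  = log  p(w_c, w_e) / ( p(w_c) · p(w_e) )
   NPMI(w_c, w_e) = PMI / ( −log p(w_c, w_e) )          ∈ [−1, 1]
   ```

   NPMI is −1 when terms never co-occur, 0 at independence, 1 at complete
   co-occurrence.
5. **Collapse & rank** — effect phrases are embedded (mean of token
   vectors), near-duplicates collapsed with DBSCAN (cosine distance,
   reachability ε = 0.1, min points 1; medoid representatives), and for a
   cause query *q* each effect is scored by the mean NPMI over
   (q ∩ V_c) × (e ∩ V_e), with per-category cumulative scores.
6. **Match** — mined effects are validated against a gold lexicon of risk
   perceptions via four match types: exact (g = e), proper (g ⊂ e),
   reverse (e ⊂ g), partial (g ∩ e ≠ ∅), with per-type coverage counts.

Annotated social-media corpora and the consumer risk-perception lexicon the
method was designed around are not redistributable, so the package includes
a first-class synthetic corpus generator with planted cause → effect
associations of known joint probability and a closed-form NPMI oracle;
a synthetic stand-in gold lexicon ships in
`examples/gold_lexicon_synthetic.csv`.  See `docs/methods.md` for the full
model description and design rationale.

## Worked example

Generate a 5 000-message corpus with five planted associations (for
instance `gardasil → premature ovarian failure` asserted in 80% of that
cause's causal messages), mine it, and rank effects for the query
"gardasil":

```python
from riskmine import GeneratorConfig, generate_corpus
from riskmine.causal import CausalCueLexicon
from riskmine.pipeline import mine_and_rank

cfg = GeneratorConfig(n_messages=5000, seed=11)
corpus = generate_corpus(cfg)
rankings, model, collapsed, pairs = mine_and_rank(
    [(m.id, m.text) for m in corpus.messages],
    cue_lexicon=CausalCueLexicon(tuple(cfg.cue_list)),
    queries=["gardasil"], alpha=1.0, top_k=5, seed=11,
)
print(f"pairs mined: {len(pairs)}; effects after collapse: {len(collapsed)}")
for surface, score in rankings["gardasil"]:
    print(f"{surface:28s} {score:+.3f}")
```

prints

```
pairs mined: 999; effects after collapse: 23
premature_ovarian_failure    +0.807
faintness_sweating           +0.036
headache_dizziness           +0.022
tenderness_rash              +0.015
redness_chills               -0.002
```

The planted effect ranks first with a strongly positive NPMI score —
`gardasil` and `premature ovarian failure` co-occur far above chance —
while the background distractor effects (which any cause may name) sit near
0, i.e. near statistical independence.  `riskmine.expected_npmi(cfg,
"gardasil", "premature")` gives the population value (0.878 under these
settings) the empirical score converges to as the corpus grows.

The same flow is available from the shell:

```bash
riskmine run --config examples/run.yaml      # full pipeline, staged artifacts
riskmine simulate --n 5000 --seed 11 --out corpus.jsonl
riskmine normalize --in corpus.jsonl --out norm.jsonl
riskmine mine --in norm.jsonl --out pairs.jsonl
riskmine rank --pairs pairs.jsonl --query gardasil
```

`riskmine run` writes every intermediate (normalized corpus, predictions,
candidate pairs, co-occurrence model, collapsed effects, rankings, match
report) into the working directory plus a `report.json` with staged filter
counts per predicted class.

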