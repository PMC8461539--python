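# Methods

`riskmine` mines the *risk perceptions* that short social-media messages
causally attribute to a vaccine, and separates perceptions circulating in
true-information messages from those in false-information messages.  The
pipeline has two halves: a supervised veracity classifier that tags messages
as true or false information with a calibratable confidence, and an
unsupervised causality miner that turns cue-bearing messages into ranked
cause → effect associations.

## Lexical normalization

Messages are normalized by an ordered rule list: lower-casing (the special
tokens `NUMBER`, `MENTION`, `RT` are exempt), URL removal, mapping of
retweet markers, user mentions and numeral runs to the special tokens,
contraction expansion from a shipped editable table, hyphen/slash splitting,
punctuation stripping, collapse of mention runs to at most two `MENTION`
tokens, and whitespace collapse.  The function is total and idempotent, and
these properties are enforced by property-based tests over arbitrary
strings.  Design choices worth noting:

* *Alphanumeric pairings* are split into their letter and digit parts
  ("2x" → `NUMBER x`); the digits then map to `NUMBER`.
* Hashtag marks are stripped but the tag text is kept as a term — the mark
  is punctuation, the content is signal.
* A retweet marker is a leading `rt` token (any case, optionally followed
  by a mention and colon).  Mid-text `rt` is left alone.
* The contraction table ships as CSV and is deliberately editable; the
  exact inventory is a free choice and the default covers the common
  English clitics plus symbol shorthands ("&" → "and", "w/" → "with").

The vocabulary assigns contiguous indices: five reserved slots (padding,
out-of-vocabulary, the three special tokens) followed by content terms in
frequency-descending, then lexicographic, order.  Frequency odds ratios
(true-category odds over false-category odds of per-message occurrence) use
the Haldane–Anscombe +0.5 correction on all four cells so they are finite
on terms absent from one category.

## Veracity classification

The primary model is a parallel-convolution text CNN: token embeddings feed
convolutions of widths 3, 4 and 5 (256 filters each by default) with ReLU
activations, global max pooling, a 128-unit ReLU dense layer with dropout
0.1, and a softmax output trained with cross-entropy under Adam (learning
rate 1e-4, decay 0.01, batch size 32).  "Decay" is interpreted as decoupled
weight decay by default; a flag (`decay_mode="lr"`) switches to
learning-rate decay.  Sequences are padded/truncated to a configurable cap
(default 64 tokens).  Training stops early on validation macro-F with
patience 5 within a 50-epoch cap, and the best-validation parameters are
restored.  A bidirectional LSTM (single layer, hidden size 64, final-state
concatenation) and two classical baselines (linear SVM and multinomial
Naive Bayes over bag-of-words counts) share the same surface.  The neural
networks are implemented directly in numpy with manual gradients (verified
against numerical differentiation in the test suite); all stochasticity —
initialization, shuffling, dropout — flows through one seeded generator, so
training is exactly reproducible.

Data splitting follows the protocol: random 60/20/20 split *first*, then
exact-text deduplication within each split, so final sizes deviate from the
nominal ratios when duplicates exist.  Evaluation reports macro-averaged
accuracy/precision/recall/F on the 0–100 scale plus the confusion matrix;
an ROC utility is included.

Word embeddings for initialization come from an unsupervised
subword-augmented trainer: a positive-PMI word–context matrix (symmetric
window of 3) factorized by truncated SVD, with character 3–5-gram vectors
(averages of the containing words' vectors) composing finite vectors for
out-of-vocabulary words.  Any object with a `vector(token)` method can be
substituted — the embedding provider is a contract, not a dependency.

The confidence filter keeps predictions whose predicted-class softmax
output reaches a threshold (default 0.998) and emits a staged per-class
accounting table (no filter / confidence threshold / contains causal cue).
The filter applies to both classes by default, restrictable to one class.

## Causality mining

A message asserts causality when it contains a cue from a plain-text cue
lexicon.  The shipped default list (cause/causes/..., lead(s)/led to,
due to, because (of), linked to, result(s) in, trigger(s), prevent(s)) is an
explicitly user-replaceable stand-in.  Cue matching is longest-first and
non-overlapping.  For each cue occurrence, noun phrases left of the cue form
the candidate cause set and phrases to the right the candidate effect set;
multi-word phrases are merged into single underscore-joined terms, and all
phrases in the message are kept whether or not they are syntactically
governed by the cue.  The parse provider is a contract (`chunk(tokens)`);
the default is a deterministic rule-based chunker that treats stopwords,
special tokens and cue words as boundaries and each maximal content-token
run as a noun phrase.  A cue with an empty side yields a *degenerate* pair,
flagged and retained rather than silently dropped.

The phrase vocabularies V_c and V_e exclude stopwords and hapax terms
(corpus frequency 1).

## Co-occurrence model and NPMI

Each candidate pair increments the joint count of every
(w_c ∈ cause ∩ V_c, w_e ∈ effect ∩ V_e) combination once (set semantics).
Probabilities come from the α-smoothed joint table normalized to sum to 1,
with marginals as row/column sums — deriving marginals from the smoothed
joint keeps them exactly consistent.  Laplace smoothing (α = 1 by default,
configurable) makes every probability strictly positive.  Then

    PMI(w_c, w_e)  = log[ p(w_c, w_e) / (p(w_c) p(w_e)) ]
    NPMI(w_c, w_e) = PMI / (−log p(w_c, w_e))   ∈ [−1, 1]

NPMI is −1 for a never co-occurring pair (α = 0 convention), 0 at
independence and 1 at complete co-occurrence (the p → 1 limit is guarded).
It is invariant to the log base; the base (default natural) only rescales
PMI.  The test suite checks the model against brute-force recounts to
1e-12, the [−1, 1] range over random tables, base invariance, and
monotonicity in the joint count.

## Collapsing and ranking

Candidate effect phrases are embedded as the arithmetic mean of their
tokens' vectors and clustered with DBSCAN under cosine distance with
reachability ε = 0.1 and minimum points 1 (so every phrase is a core point
and none is noise).  Cosine distance is a design choice: the stated ε of
0.1 is implausible for unnormalized Euclidean distances on dense
embeddings; the metric is switchable.  Because min-points 1 makes "cluster
core" non-unique, the representative is the cluster *medoid* (minimum
summed cosine distance to members; ties broken by higher phrase frequency,
then lexicographically) — deterministic and always a member.  The default
embedding provider is a seeded hashing provider (unit vectors from a salted
token hash): it carries no semantics but is fully reproducible without
model downloads; a contextual-transformer provider can be dropped in via
the same contract.

Ranking is retrieval: a query q (a normalized term set naming a cause)
scores each surviving effect e by the mean NPMI over all
(w_q ∈ q ∩ V_c) × (w_e ∈ e ∩ V_e) pairs.  Out-of-vocabulary pairs are
skipped by default (`oov_mode="zero"` counts them as 0); an effect with no
scorable pair is flagged undefined and excluded.  Ties break
lexicographically, so rankings are deterministic and permutation-invariant.
Per-category cumulative scores sum member effects' scores and retain the
per-effect contributions for stacked-bar style reporting.

## Gold-lexicon matching

A mined effect e is compared with a gold phrase g on normalized,
stopword-free term sets under strict precedence: **exact** (g = e) >
**proper** (g ⊂ e: the mined phrase is a more specific instance, as with
mined "early onset menopause" against gold "menopause") > **reverse**
(e ⊂ g, mined "fatigue" against gold "extreme fatigue") > **partial**
(g ∩ e ≠ ∅, mined "prevent throat cancer" against gold "prevent cervical
cancer") > none.  Coverage statistics are non-exclusive per gold phrase
across candidates: a gold phrase counts toward every type some candidate
achieves, so type tallies may overlap; the partial-or-proper union is
counted as distinct gold phrases.  Stemming before comparison is available
but off by default.

## Synthetic corpus generator

Real annotated vaccine-discourse corpora and the consumer risk-perception
lexicon used for validation are not redistributable, so the generator
produces corpora with the statistical structure the pipeline assumes, plus
analytic oracles.  What it emulates:

* **Two veracity classes.**  False-information messages over-sample a
  false-discriminative vocabulary ("danger", "adverse", "deadly", ...),
  true messages a true-discriminative one ("prevent", "protect",
  "effective", ...), over a shared topical vocabulary; each filler token is
  discriminative with probability 0.35.  Class prevalence defaults to 43%
  false, modelling a misinformation-heavy discourse.
* **Causal assertions.**  A fifth of original messages (default) are
  minimal causal assertions "the CAUSE CUE EFFECT..." — short and formulaic
  by design, so each assertion contributes exactly one (cause term, effect
  phrase) observation and the population NPMI has a closed form.  The
  association index is uniform over the K planted associations; with
  probability `joint_boost` the assertion names the association's planted
  effect phrase, otherwise one of 20 background distractor effects
  (side-effect vocabulary disjoint from every planted term).  Default
  boosts: 0.8/0.7/0.6/0.5/0.4 across five associations.
* **Duplicates.**  A quarter of the stream (default) is exact copies of
  earlier originals with fresh ids, emulating retweets and exercising the
  split-then-dedupe accounting and the collapse stage.
* **Noise.**  URLs, leading retweet markers, @-mentions, hashtags,
  numerals, random casing and punctuation are injected so every
  normalization rule does real work.  On causal assertions, insertions are
  restricted to the front so the cause → cue → effect structure stays
  contiguous.

`expected_npmi` returns the population NPMI implied by these probabilities
without smoothing.  For association a with boost b among K associations:
p(cause) = 1/K, p(effect) = b/K, p(joint) = b/K, giving
NPMI = ln K / (ln K − ln b); cross-association pairs never co-occur (−1),
and with K = 1 the joint equals the product of marginals (0).  An
integration test mines a 100 000-message corpus through the real
normalization/extraction/counting chain and checks every planted
association against the closed form within ±0.05.

When comparing mined NPMI against the oracle, mining uses the corpus's own
cue list (the generator's `cue_list`): the shipped default cue lexicon also
contains "prevent(s)", which legitimately appears in true-class filler
text, and assertions mined from filler are outside the closed-form model.
This mirrors real practice — the cue dictionary is an input matched to the
study, not a constant.

**What the generator does not emulate:** network structure, timestamps and
user metadata; topic drift; near-duplicates (only exact copies); label
noise; causal assertions embedded mid-sentence in longer discourse; and
class-informative causal assertions (assertion messages carry no
discriminative vocabulary, so they are intrinsically hard for the
classifier).  Passing tests therefore demonstrate the pipeline's mechanics
and statistical behavior under known structure, not performance on real
social-media text.

## Benchmark problem sizes and numerical choices

The package's standing benchmarks are sized for a single CPU: the
classifier sanity benchmark trains the CNN on a 2 000-message separable
corpus (disjoint class vocabularies, no causal assertions) with a scaled
architecture — embedding 48, 64 filters per width, dense 32, learning rate
1e-3, epoch cap 30 — and requires held-out macro-F ≥ 95 with exact
reproducibility per seed; association recovery generates 20 corpora of
5 000 messages (seeds 0–19) and requires every planted effect in its
cause-query's top 10 in ≥ 95% of seeds; collapsing fidelity requires 200
phrase embeddings (20 planted phrases × 10 sub-ε perturbed duplicates) to
collapse to exactly 20 representatives.  The full-size architecture
defaults (embedding 300, 256 filters, dense 128, learning rate 1e-4)
remain the package defaults for real corpora.

Degenerate inputs are defined, not crashed on: empty messages normalize to
empty token lists and predict the training majority label at confidence
0.5 with a warning; a cue at a message boundary yields a flagged degenerate
pair; an all-out-of-vocabulary effect is excluded from rankings with a
diagnostic; an empty candidate set produces a zero-coverage match report
with a warning.  Floating-point NPMI is clipped to [−1, 1] to absorb
rounding overshoot at the boundaries.

## Known limitations

* The rule-based chunker has no part-of-speech knowledge; verbs inside a
  content-token run merge into the phrase.  The parse provider contract
  exists precisely so a statistical parser can replace it.
* The hashing embedding provider clusters only exact-duplicate phrases
  (identical vectors); semantically similar but lexically different phrases
  collapse only with a semantic provider.
* SVM confidences are a logistic transform of the margin, not calibrated
  probabilities; the 0.998-style threshold is meaningful mainly for the
  softmax models.
* With weight decay interpreted as decoupled decay, reported results are
  not comparable to an implementation reading it as learning-rate decay;
  the flag exists but defaults matter.
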