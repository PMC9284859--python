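# Methods

This note records the modelling choices behind `premnlp`, their
defaults, and what the synthetic benchmarks do and do not demonstrate.

## Data model

An answer is one document, keyed by (respondent, question), stored
verbatim. Empty and whitespace-only answers are kept in the corpus —
they belong in the per-question denominators — but are excluded from
classifier training and topic modelling and receive the neutral label
at prediction time. Sentiment is assigned per answer, not per
sentence; answers that mix a positive and a negative clause therefore
get a single label, which is the main known source of label noise on
real data.

## Sentiment cascade

Two binary stages rather than one three-class model: stage A (negative
vs non-negative) sees every labelled answer; stage B (positive vs
neutral) is trained only on the answers whose gold label is
non-negative, mirroring exactly what it will see at inference. The
cascade guarantees that the negative decision is owned by a single
model — useful because negative feedback is the rare, operationally
critical class.

The backend contract is `fit(texts, labels)` / `predict(texts)` with a
determinism requirement given a seed. The default backend is TF-IDF
(1–2-grams) + logistic regression (C = 10, lbfgs, max_iter 1000): on
short answers a linear bag-of-words model is a strong baseline, has no
pretrained-weight dependency, and keeps the cascade — the part that
matters — backend-agnostic. A transformer backend can implement the
same contract.

Training uses a seeded 80/20 shuffle split (`split_fraction = 0.8`);
held-out precision/recall/F1 are reported per stage. A stage whose
training subset contains a single class raises a degenerate-training
error naming the stage rather than fitting silently.

## Preprocessing

Pipeline order: tokenize → spelling-correct → lemmatize → filter →
vectorize. Tokens are lowercased Unicode letter runs; digits and
hyphens split tokens.

Spelling correction is the classic Norvig single-token corrector: a
token already in the frequency lexicon is kept; otherwise the
highest-frequency lexicon word among its edit-distance-1 candidates
(deletion, transposition, substitution, insertion), then
edit-distance-2, then the token unchanged. Frequency ties break
lexicographically so runs are reproducible. The candidate alphabet is
derived from the lexicon, so the corrector is language-agnostic; the
lexicon is an input file, never built in.

Filtering drops stopwords (input list), lemmas shorter than 3
characters (`min_word_length = 3`), and lemmas whose POS tag is not
verb/adverb/noun/adjective. The lemmatizer/tagger is a plugin; the
default rule-list plugin is an identity lemmatizer that tags unlisted
words as nouns, i.e. a no-op unless rules are supplied. A model-based
tagger (e.g. Stanza for Dutch) can be adapted to the same
`analyze(token) -> (lemma, pos)` interface.

TF-IDF uses raw term counts, idf(t) = ln((1+N)/(1+df(t))) + 1 and
L2-normalised rows (the common smoothed dialect), over all contiguous
1–3-grams of the *filtered* token sequence — gaps left by removed
tokens close up. `min_df` defaults to 1; per-stratum analyses use
`min_df = 2` in the examples to prune singleton n-grams. All dialect
parameters are recorded in the `VectorSpace.params` mapping. Documents
emptied by filtering keep an all-zero row and are flagged, which is
what later makes them "unassigned" rather than silently dropped.

## Topic models

One NMF per (question × sentiment) stratum; neutral answers carry no
actionable direction and are excluded from strata. The factorisation
minimises the Frobenius error with Lee–Seung multiplicative updates,
NNDSVDa initialisation (deterministic, SVD-based; zeros filled with
the matrix mean), `max_iter = 400`, and a relative-improvement
stopping tolerance of 1e-4 checked every 10 iterations. The residual
trajectory is logged and is non-increasing by construction, which the
tests assert. An all-zero matrix short-circuits to zero factors.

The number of topics is selected by refitting independently (no warm
starts) for every k in 2…15, clipped to min(n_docs, n_terms). Model
coherence is a two-level mean: per topic, the mean pairwise cosine
between the embedded top-10 terms (an n-gram embeds as the
renormalised mean of its in-vocabulary word vectors; terms with no
known word are skipped; fewer than two embeddable terms give 0); per
model, the mean over topics. The highest coherence wins, ties to the
smaller k, and the full (k, coherence) log is kept in the result
manifest. Pairwise cosine treats exact matches (cos = 1) and synonyms
(high cos) uniformly, which is the intent of an embedding-based
coherence.

Assignment is argmax over the document's W row; ties take the lowest
topic index; an all-zero row is unassigned (no minimum-weight
threshold by default — a threshold would add a parameter the method
does not need; one can be layered on top of `assign_topics`).

Descriptors: the ten highest-weight n-grams (weight ties
lexicographic), sorted by word count descending (stable), then any
term whose token sequence is an ordered — not necessarily contiguous —
subsequence of a longer retained term is removed, and the first five
survive. The ordered-subsequence rule is what keeps "went well" out of
a list that already contains "went very well"; it strictly subsumes a
contiguous-substring rule.

## Validation statistics

Audit sampling per (stratum, topic): all answers when the topic holds
fewer than `min_n = 10`, otherwise max(⌈0.2·n⌉, 10), drawn without
replacement with a seeded generator. Ceiling rounding: a stated
minimum should never be undercut. Representativeness rates pool counts
(Σ fits / Σ judged) at the stratum and overall levels — a mean of
per-topic rates would over-weight small topics.

Topic overlap takes the human-produced matching as input and computes
only |distinct matched manual topics| / |manual topics|; the matching
itself is expert judgment, not an algorithm.

The structured-score comparison is an independent-samples t-test per
question between positive- and negative-classified respondents,
pooled-variance (Student) by default with Welch selectable; the
variant is recorded in every output row. It accepts raw scores or
summary form (n, mean, sd). No multiple-testing correction is applied
across questions, and the output metadata says so.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the structural features of a short open-ended
experience survey: answer lengths from a discretised log-normal with
median 2 and upper quartile 11 (µ = ln 2, σ = ln(5.5)/0.6745), clamped
to [1, 192]; a positive-dominated sentiment mix (default 62/8/20/10
positive/negative/neutral/empty); planted topics as pairwise-disjoint
word lexicons per stratum; sentiment marker words; background noise
words; optional single-edit typo injection at a configurable rate; and
embeddings in which same-group words have a controlled expected cosine
(default 0.8) while unrelated words are near-orthogonal (dimension 50).
All randomness flows from one seed through named substreams.

Two deliberate design points:

- **Planted words are ≥ 3 edits apart** (tripled index letters,
  three-letter sentiment codes at pairwise distance 3), so a
  single-character typo is always closer to its own original than to
  any other vocabulary word. Without this the typo-recovery ceiling is
  set by vocabulary density, not by the corrector.
- **Topic lexicons hold 6 words**, fewer than the 10-term
  coherence/descriptor window. A component that blends two planted
  topics then necessarily shows words of both groups among its top ten
  terms and is penalised by near-zero cross-group cosines; with larger
  lexicons a blended component can fill its window from one group and
  under-selection of k becomes invisible to coherence.

What the generator does **not** model: grammar or morphology (words
are synthetic letter strings), per-question length differences,
overlapping topic vocabularies (an overlap knob exists but defaults to
disjoint), mixed-sentiment answers, and annotator disagreement.
Passing the planted-structure benchmark therefore shows that the
pipeline recovers structure that is present and separable; it does not
predict performance on real clinical text, where class imbalance,
synonymy and mixed sentiment dominate the error budget.

## Benchmark problem sizes

The planted-structure benchmark uses a single-question corpus of 450
respondents (≈ 200 documents per sentiment stratum after the 45/45/5/5
mix), 4 planted topics per stratum, within-group embedding cosine 0.8,
`min_df = 2`, and 10 independent seeds; the sentiment macro-F1 is
computed over all non-empty answers with the cascade trained on 80% of
the gold labels. These sizes keep a full 10-seed run around ten
seconds while leaving each stratum large enough that k-selection is
driven by structure rather than sampling noise.

## Known limitations

- Coherence-based k selection is only as good as the embeddings; with
  a poor embedding table the log shows near-flat coherence across k
  and the tie rule (smallest k) dominates.
- The default rule-list tagger keeps everything unless told otherwise;
  on real Dutch text the Stanza adapter (not shipped) or a stopword
  list is needed for the POS filter to bite.
- Multiplicative-update NMF converges to local minima; runs are
  deterministic, but a different initialisation scheme would give
  different (equally valid) factors.
- The t-test on structured scores inherits the sentiment classifier's
  errors: misclassified respondents dilute the group contrast.
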