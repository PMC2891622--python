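# Methods

## The task

Evidence-based practice frames clinical questions in PICO form:
Population/Problem, Intervention, Comparison, Outcome.  Finding the
sentences of a MEDLINE abstract that state each element is a prerequisite
for clinical question answering and systematic-review screening.
`picosense` treats this as sentence-level binary classification, one
classifier per element, with the Comparison element merged into
Intervention: when a trial compares two drugs, which arm is "the"
intervention is usually undecidable, and both belong to the same semantic
group of exposures.

## Distant supervision

Hand-labeling abstracts at scale is prohibitively expensive, so training
data is constructed from *structured* abstracts — those whose authors
wrote explicit section headings such as `PARTICIPANTS:` or
`MAIN OUTCOME MEASURES:`.  The rules are deliberately conservative:

* A sentence opens a PICO section when it begins (after optional list
  markers) with a heading from the per-element lexicon followed by a
  colon, matched case-insensitively and longest-first (`MAIN OUTCOME
  MEASURES` before `OUTCOME`).  Non-PICO headings (`METHODS:`,
  `RESULTS:`, ...) are recognised only for stripping, never for labeling.
* Exactly **one** gold sentence per element per abstract: the sentence
  sharing the heading, or the next sentence when the heading stands
  alone.  Labeling everything below a heading imports too many false
  positives, because section boundaries in prose are vague; one sentence
  is restrictive but clean.
* If the same element's heading appears twice, the first wins.
* Abstracts with no PICO heading are excluded; an abstract may be
  labeled for any non-empty subset of {P, I, O} (Outcome headings are
  the rarest).

After labeling, *all* headings are stripped and empty heading-only
sentences dropped (gold indices remapped), so that features are computed
on text that looks unstructured.  Otherwise the cue-word features would
be trivially biased by the very headings that produced the labels.

The heading lexicon ships as an editable TSV.  Only part of any such
list is ever published; the shipped entries are seed values and a user
can extend them without touching code.

## Sentence segmentation

No standard segmenter is assumed.  The built-in splitter cuts after
`.!?` when the next token looks like a sentence opener, guarded by a
clinical abbreviation list (`vs.`, `e.g.`, `i.p.`, single initials,
decimals), and additionally starts a new sentence before an ALL-CAPS
heading followed by a colon even without a terminator.  Segmentation is
total, deterministic, and lossless up to whitespace.  Because published
corpus statistics always depend on the (never published) segmenter used
to produce them, sentence counts are not comparable across
implementations; all evaluation here is relative to this segmenter's
output.

## Canonicalization and lexical resources

Tokens are lowercased; cardinal number words up to 999,999, hyphenated
compounds included, become digit strings ("twenty-five" → "25";
ordinals stay words); alphabetic tokens pass through a small suffix
stemmer iterated to a fixpoint, which makes canonicalization idempotent
by construction.  The stemmer is deliberately crude (it only needs to
collapse inflectional families like randomize/randomized/randomizing);
it over-stems occasionally, which is harmless because every resource is
canonicalized with the same function at load time.

Three resources drive the knowledge-based features:

* **cue-verbs** (conduct, recruit → P; randomize, prescribe → I;
  assess, record → O) and **cue-words** (population, group → P;
  placebo, treatment → I; mortality, outcome → O), shipped as a seed
  TSV with a few same-spirit extensions;
* three **semantic-type term lists** in the MeSH/UMLS groups Living
  Beings, Disorders, and Chemicals & Drugs.  The full lists (hundreds to
  tens of thousands of terms) derive from a licensed MeSH/UMLS release
  and are not redistributable; a demonstration slice ships with the
  package, with the UMLS type identifiers kept as metadata, and the TSV
  format accepts a user's own export.

Multi-word terms are matched greedily, longest-first, left to right,
each token consumed at most once.  Note a consequence: adding a longer
term to a list can *lower* the match count (a bigram absorbs what two
unigrams counted separately), so term counts are only monotone under
additions over fresh vocabulary.

## Features

Each sentence maps to a fixed 17-dimensional vector:

| feature | definition |
|---|---|
| `pos_abs` | 0-based sentence index |
| `pos_rel` | index / (N−1); 0 for a single-sentence abstract |
| `sent_len` | word-token count |
| `n_punct` | punctuation marks in `,;:.!?()[]"'%/-−` |
| `n_num_gt10`, `n_num_lt10` | numeric tokens with value > 10 / < 10 (exactly 10 counts in neither) |
| `title_overlap` | distinct canonical non-stopword tokens shared with the title |
| `cue_words_P/I/O`, `cue_verbs_P/I/O` | cue-lexicon match counts |
| `mesh_1/2/3` | semantic-list match counts |
| `n_pattern` | occurrences of `( n = digits )` |

Choices where the design was open: `pos_rel` uses the N−1 denominator so
first = 0 and last = 1; sentence length counts tokens, not characters;
semantic matches are counts, consistent with the other "number of"
features; percentages count by their numeric value.  No bag-of-words and
no part-of-speech features, so no tagging errors can propagate.

## Classifiers

Five base learners behind one train/score contract (each yields a score
in [0, 1] and a binary decision per sentence), implemented on
scikit-learn:

* decision tree (C4.5-style), Gaussian naive Bayes, random forest
  (100 trees) — scale-invariant, used unscaled;
* RBF-kernel SVM (C = 1, gamma = "scale") and an MLP with one hidden
  layer of ⌈(17+2)/2⌉ = 10 units and a fixed iteration cap of 150 —
  both behind a standardizing scaler.  The kernel description this
  reproduces ("radial kernel of degree 3") is ambiguous, since degree
  is a polynomial-kernel parameter; an RBF kernel with conventional
  defaults is used and the ambiguity recorded here.

The SVM is **binary-scored by default**: its class prediction is its
score, so within an abstract it cannot rank two accepted sentences
apart.  This is kept deliberately — it produces the characteristic flat
behaviour across n-best cut-offs — and a Platt-calibrated probability
mode is available via `hyperparameters={"probability": True}`.
Probabilistic learners decide at score ≥ 0.5.  Class imbalance (~1
positive in ~13 sentences) is left unresampled by default; a
`balanced` class-weighting flag exists.

The **position baseline** stores the median relative position of the
gold sentences and always labels exactly the one sentence nearest that
median.  One prediction per abstract forces precision = recall =
f-measure — the structural signature by which such a baseline is
recognisable in any results table (micro-f is computed as
2·TP/(2·TP+FP+FN), which makes the identity exact in floating point).

## Fusion

Per abstract, the five classifiers' outputs form a score matrix
(classifiers × sentences) and combine three ways:

* **F1, voting** — a sentence is a candidate iff a *strict* majority
  (> K/2, i.e. ≥ 3 of 5) of classifiers labels it; among candidates the
  larger mean score wins, ties to the lower index; no candidate means
  abstention.  Votes dominate scores: the combined ranking key is
  (votes + mean score)/(K + 1).
* **F2, equi-probable linear** — the mean of the five scores.
* **F3, rank-weighted linear** — weights fixed by the observed
  f-measure ranking of the base classifiers: best of K gets K, next
  K−1, ..., worst 1; exact ties share the mean of the tied ranks.
  Weights are per element, stored unnormalized, and normalized to sum 1
  at use, so fusion is invariant under positive rescaling; uniform
  f-measures make F3 collapse to F2 exactly.

The linear fusers decide like the probabilistic learners: predict the
argmax sentence when its combined score reaches 0.5, else abstain.
Some threshold must exist for precision and recall to diverge, and 0.5
is the same convention the base learners use.

## Decoding and evaluation

`single` decoding predicts the argmax sentence if its decision fires,
else abstains; `nbest` predicts the top n sentences by score, ties to
the lower index, **excluding zero-scored sentences** — a scorer that
assigns 0 has rejected the sentence and cannot rank it, so padding the
prediction with indistinguishable rejects would be meaningless.  This
exclusion is what keeps the binary-scoring SVM constant across
cut-offs while every probabilistic method's recall rises.

A prediction is correct iff it equals the gold index.  Counts pool over
abstracts (micro-averaging): TP = predicted indices equal to gold,
FP = other predicted indices, FN = gold sentences never predicted;
precision under total abstention is defined as 0, penalizing a system
that never commits.  n-best precision counts all n predicted sentences
in its denominator.

Cross-validation partitions **abstracts** (never sentences, which would
leak context) into k = 10 near-equal folds by a seeded shuffle.  Within
each fold the training portion is split 90/10: base models fit on the
90%, their single-mode f-measures on the held-out 10% fix the F3 rank
weights for that fold, and those same models score the test fold.
Deriving the ranking from training data only avoids leakage; reusing
the inner-90% models for testing costs a sliver of training data and
halves the fitting work.  Reported metrics are the mean over folds; a
`repeats` option re-partitions and averages again.  Everything is
deterministic given the seed.

## The synthetic corpus

No clinical corpus is distributable, so the generator fabricates
structured abstracts with the properties the pipeline consumes:
8–18 sentences (mean ≈ 13, the sentence density implied by
heading-selected RCT corpora); objective/methods/results/conclusion
filler around P → I → O sections placed by per-element position priors
(relative positions ≈ 0.25/0.45/0.65, σ = 0.08, always in canonical
order); gold sentences drawing cue words, cue verbs and semantic-list
terms with probability `cue_signal` per slot (default 0.9); large
enrollment counts and `(n = ...)` patterns in Population sentences;
titles sharing tokens with gold sentences.  Element inclusion rates
default to 0.95/0.85/0.70 for P/I/O, reflecting that Outcome headings
are the rarest in real harvests.  Filler is adversarial the way real
abstracts are: numbers appear outside the Population sentence, and cue
vocabulary leaks into non-gold sentences (30% of filler sentences carry
1–2 cue-word distractors).  Label noise defaults to 0 — heading-based
extraction is designed to be low-noise — and can be raised to study the
distant-supervision failure mode (heading on an uninformative sentence,
informative sentence adjacent and unheaded).

What the generator does **not** emulate: grammar, discourse structure,
synonymy and paraphrase, multi-sentence outcomes, or the vocabulary
ambiguity of real drug and disease names.  Passing tests on this corpus
therefore demonstrate that the pipeline's machinery is correct and that
its learners recover a planted signal through the feature scheme — not
that the same f-measures would be obtained on real abstracts, where the
lexical signal is far weaker and noisier.

## Problem sizes and numerical choices

The test suite's heaviest check cross-validates the full pipeline on
corpora of 2,000 synthetic abstracts (≈ 26,000 sentence instances),
10 folds, averaged over 5 generator seeds; the cut-off study uses 600
abstracts, and the distant-supervision recovery check 1,000.  The
acceptance script uses 1,000 abstracts and 10-fold CV per element.
These sizes give stable means (fold-to-fold f-measure spread well under
the margins asserted) at desk-scale runtimes.

Degenerate inputs are pinned down: empty text segments to an empty
list; a single-sentence abstract has `pos_rel` = 0; empty datasets and
single-class training raise; all-zero fusion weights raise; total
abstention scores 0, not 1.  Ties break toward the lower sentence index
everywhere, and every stochastic component (generator, fold shuffle,
learner initialisation) is driven by an explicit seed.

## Known limitations

* One gold sentence per element is wrong for Outcomes, which typically
  span two or three sentences — the reason the n-best cut-off
  evaluation exists at all.
* The shipped heading, cue and semantic lists are seeds, not the full
  curated resources; recall on real text depends directly on their
  coverage.
* Gaussian naive Bayes degrades sharply when distractor vocabulary is
  dense (its independence assumption is badly violated by correlated
  count features); it remains the weakest base learner by design of the
  comparison, not a defect of the harness.
* The suffix stemmer is English-only and aggressive; the number-word
  parser does not handle multi-token spelled-out numbers ("two hundred
  and six" as three tokens).
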