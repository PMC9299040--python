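# Methods

## Problem setting and model

An update search re-runs a systematic review's search strategy at a
later date under unchanged eligibility criteria. The original review
contributes a labelled corpus (every title/abstract screened
include/exclude, often with hierarchical exclusion codes); the update
contributes an unlabelled corpus from the same topical distribution.
`citescreen` fits a discriminative model to the original decisions and
uses it to bound screening of the update.

The classifier is a linear logistic-regression model over raw counts
of word n-grams, fitted by stochastic gradient descent
(scikit-learn's `SGDClassifier` with log loss and its default
hyper-parameters: alpha 1e-4, max 1000 epochs, tolerance 1e-3; all
recorded in the serialised model). Featurisation choices, and why:

* **unigrams–trigrams** (`ngram_min=1, ngram_max=3`): trigrams are
  what let the model treat "randomized controlled trial" as one
  signal; retaining the lower orders keeps coverage when a trigram is
  unseen. The range is configurable and stored with the model.
* **no stemming**: "trials" vs "trial" separates reviews discussing
  many trials from reports of one trial. A `stemming=True` flag is
  deliberately rejected rather than silently ignored.
* **PubMed stop words removed before n-gram formation** (so "risk of
  bias" → "risk bias"). The bundled list is NLM's historical PubMed
  stop-word list (133 terms), shipped as a plain-text data file.
* **raw term counts**, no tf-idf: counts are the minimal bag-of-words
  reading; the featuriser is isolated behind `FeatureConfig` so a
  weighting scheme can be added without touching the model.
* **class weighting off by default**; `class_weight="balanced"` is
  available for experimentation with very broad include rules.

Scores are `floor(100 p)` capped at 99 — the only rounding that maps
p = 1 into the stated 0–99 range without a special case. Scoring is
reproducible: ranking ties break by ascending record id, training is
bit-identical for a fixed seed, and models serialise to a
self-describing JSON archive (weights stored as hex floats, so
save/load round-trips exactly).

## Screening policy and simulator

`ThresholdPolicy(low_cut=10, high_cut=20, batch_size=500,
stop_interval=1000, floor_score=None)` partitions a ranking into
never-screen / always-screen / batched-middle zones. The simulator
maintains one counter: consecutive screened non-includes since the
most recent include. Design points that were genuinely open:

* the counter accumulates through the always-screen zone ("since the
  last include", wherever it occurred) but can only terminate
  screening in the middle zone; `count_priority_zone=False` restricts
  it to the middle zone for users who read the interval rule as
  zone-local;
* stopping is evaluated at batch boundaries, not mid-batch, because
  screening is distributed to humans batch-wise; the interval check
  takes precedence when both it and the floor trigger at the same
  boundary;
* records without abstracts are split out before ranking
  (`split_by_abstract`) and treated as an always-screen-manually
  list — a five-word title is not enough text to trust a score.

## Evaluation conventions

Precision is computed over screened (threshold-retained) records,
recall over all known relevant records, screening reduction over all
scored records; these conventions make the three quantities mutually
consistent with the workload identity reduction + screened% = 100.
Percentages are kept unrounded internally; presentation rounds
reduction/recall to whole percent and sub-1% precision to 2 dp.
Stratified k-fold recall (default k=5) uses scikit-learn's seeded
`StratifiedKFold`; a held-out positive counts as recalled iff its
score ≥ the stated threshold. Per-band screening-time summaries
report the mean to 1 dp and exact totals; hours saved =
unscreened × seconds-per-record / 3600, rounded to the nearest hour,
with the seconds-per-record taken from measurements at the low scores
actually forgone.

The **suitability check** formalises the bar-chart heuristic used to
decide whether a classifier is usable at all: suitable iff the 0–9
decade bin exceeds both the 10–19 and the 20–29 bins, and no bin from
the 20s upward exceeds its left neighbour by more than
tolerance × count(0–9) (default tolerance 0.10). The slack is
expressed relative to the dominant low bin so that the small bump of
genuine includes at the top of the scale — visible whenever prevalence
is not minuscule — does not trip the decay clause, while a
distribution with its mass shifted into the 10–29 range is flagged.

## Synthetic corpus generator

`CorpusSpec` draws word-like tokens (CV-syllable strings, Zipf
frequencies, exponent 1.1) from three pools: a background pool (2,000
types) and include-/exclude-tilted pools (150/300 types). Each token
of a record comes from the record's own class pool with probability
`separability`, otherwise from the shared vocabulary (a pool chosen
proportional to size, then Zipf within it) — so at separability 0 the
classes are statistically identical and at 0.9 they are nearly
disjoint. Defaults describe a realistic update-search corpus: 5,000
records, 2% include prevalence, titles of 5–15 tokens, abstracts
~N(120, 40) tokens floored at 40, and three injected defect classes on
disjoint record subsets — 7.7% title-only, 25% abstract-in-notes, and
0.25% unlabelled near-duplicates whose titles differ only in case,
punctuation or whitespace. The defect fractions mirror the corpus
proportions reported for a real pharmacy-public-health update search;
the floor of 40 abstract tokens keeps every misplaced abstract above
the 200-character repair heuristic, making repair/dedup closures
exactly testable. Everything is deterministic in `spec.seed`, and the
manifest (spec + altered record ids) regenerates the corpus
bit-identically.

What the generator does **not** emulate: real lexical semantics,
topic drift between original and update, conference-abstract noise,
or borderline records that humans disagree on. Two corpora generated
with different seeds share no vocabulary, so train-on-A/score-B across
seeds is meaningless; the update-search analogue is a held-out split
of one corpus. Passing tests on this generator therefore demonstrate
the correctness and determinism of the machinery and the qualitative
recall/reduction regime — not recall levels on any real corpus.

## Numerical and degenerate-input choices

Tokenisation splits on non-alphanumeric boundaries and case-folds
before stop-word comparison. Vocabulary order is lexicographic, making
refits identical. Records whose configured fields yield no tokens are
dropped from training with a warning and, at scoring time, scored from
the intercept alone and flagged. Empty corpora are format errors on
read and value errors on write; an empty screening plan is valid and
screens nothing. Deduplication keys on the case-folded,
punctuation-stripped, whitespace-collapsed title plus the year when
both records have one (a missing year matches any); the kept
representative prefers labelled over unlabelled, then
abstract-bearing, then first-seen.

## Known limitations

* The score-histogram suitability heuristic cannot detect a poorly
  separating classifier at very low prevalence: an (unweighted)
  logistic model calibrated near a 2% base rate scores almost every
  record below 10 regardless of how well it ranks, so the histogram
  stays L-shaped even for a near-chance classifier. The pathological
  pattern the heuristic does catch — mass in the 10–29 bins exceeding
  0–9 — arises in practice from broad or noisy include rules rather
  than from weak separability. Cross-validated recall, not the
  histogram, is the reliable selection signal in the low-prevalence
  regime.
* SGD-fitted probabilities on high-dimensional sparse n-grams
  saturate: scores bunch near 0 and 99, so the 11–19 middle zone can
  be nearly empty on easy corpora and the batch/interval rules only
  bite when ranking quality is genuinely poor.
* The time-saved estimate extrapolates a mean of five stopwatch
  measurements and ignores fatigue, breaks and screening at scale; it
  is an order-of-magnitude figure.
* Deduplication is exact-key only (no edit-distance matching), by
  design, so its guarantees are provable.

## Problem sizes used in the checks

The automated checks run the full pipeline on corpora of 5,000
records (2% prevalence) over ten seeds for the recall/reduction
regime, five seeds per separability for suitability verdicts, 120
random texts against the brute-force featurisation oracle, and 60
random instances of ≤ 200 records against the literal replay oracle of
the stopping rules — sizes chosen so the whole suite completes in a
few minutes on one CPU while keeping ≥ 90 includes per corpus.
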