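# Methods

## The classification problem

A surveillance site holds, for each 8-year-old child flagged by record
review, a set of free-text developmental evaluations from school and health
sources, and (for clinician-reviewed years) a binary surveillance case
determination. The package learns the mapping from evaluation text to that
determination on one labeled year and applies it, frozen, to later years.
The unit of classification is the child: all of a child's evaluations are
concatenated into a single document before feature extraction, in a
canonical order (ascending age at evaluation, ties by source name then
input order, single-space separated). Order only matters for byte-level
reproducibility of artifacts; the features are order-free.

## Text features

Tokenization keeps maximal runs of letters (digits, punctuation, hyphens
and apostrophes act as separators), lower-cases, and stems with the Porter
(1980) algorithm as implemented in `asdsurv.stem`. The one departure from
the 1980 paper is the standard revised step 1c: terminal `y` becomes `i`
only when preceded by a non-initial consonant, so `happy → happi` but
`play → play` (the original rule maps both `playing` and `played` to
`plai`). Stemming is deterministic and identical at train and predict
time (the stemmer id is recorded in the model artifact); the exact stem
spellings are otherwise immaterial.

Features are all contiguous 1–3-word phrases of stemmed tokens. No
stop-word removal is applied. A phrase enters the vocabulary when it occurs
in at least `ceil(N × min_df_fraction)` child documents (default 3%; a
tiny epsilon guards the ceiling against binary floating-point overshoot so
100 × 0.03 → 3). Document frequency is always counted on child-level
documents, not individual evaluations.

Counts are weighted by TF-IDF in the classic text-mining form: relative
term frequency within the child's document times `log2(N / df)`. The
relative frequency denominator is the row sum of the count matrix (all
vocabulary terms, n-grams included). A term present in every document gets
zero weight; a document with no vocabulary terms is an all-zero row. When
a new year is transformed, `N`, `df` and the vocabulary are the frozen
training values. Alternatives (raw counts before IDF, natural-log IDF,
length norms) would be one-line changes in `apply_tfidf`; the package
commits to a single variant so that train/predict are always consistent.

## Classifier

Random forest (scikit-learn), classification defaults for everything
except tree count. Three stages:

1. **Ranking.** A forest of `n_trees_selection` trees (default 10,000) is
   grown on the full TF-IDF matrix. Term importance is Breiman's OOB
   permutation importance — for each tree, the accuracy on its out-of-bag
   rows minus the accuracy after shuffling one term's column within those
   rows, averaged over trees. Terms a tree never splits on contribute
   exactly zero for that tree and are skipped. Ties in the ranking break
   lexicographically, making the ranking fully deterministic under the
   seed.
2. **Subset search.** Nested top-k subsets of the `k_candidates` = 175
   highest-ranked terms (k = 5, 10, …) are each scored by the OOB accuracy
   of a forest of `n_trees_final` trees refit on those columns. The
   smallest k within `selection_tolerance` (default 0.005 absolute) of the
   best observed accuracy wins. This is an explicit, auditable rule for
   reducing 175 candidates to a parsimonious final term set; the number
   selected depends on the data (synthetic corpora typically select far
   fewer than real surveillance text would).
3. **Final refit and calibration.** The final forest (default 3,000 trees)
   is refit on the selected terms. The vote-share cutoff is the training
   non-case fraction, `(n_total − n_case)/n_total` — 0.483 for a
   601-case/1162-child year — instead of the majority default 0.5, so that
   the predicted case fraction is anchored to the training class balance.
   A score exactly at the cutoff classifies as a case.

Per-tree OOB membership is reconstructed from each tree's recorded seed
(`RandomState(seed).randint(0, n, n)`, the identical draw the library
makes at fit time) because scikit-learn exposes neither per-tree OOB votes
nor Breiman-style OOB permutation importance; the reconstruction is
verified against the library's `oob_decision_function_` in the tests.
OOB classification scores are vote fractions among the trees for which
the row was out-of-bag; rows never out-of-bag (probability (1−1/e)^trees,
negligible for hundreds of trees) score 0.5 and are logged.

One master seed fans out to per-stage seeds via `SeedSequence`, so every
stochastic stage is independently reproducible.

At prediction time, children whose documents contain none of the model
terms are scored on an all-zero row (the forest's constant prediction for
that region) and logged, never dropped.

## Evaluation layer

Agreement, sensitivity, specificity, PPV, NPV are computed in exact
rational arithmetic (`fractions.Fraction`) from the 2×2 concordance counts
and rounded only for display (percentages to 1 decimal, kappa to 2, AUC
to 3); unrounded values are always available. Cohen's kappa uses the
marginal-product expected agreement. Metrics with zero denominators are
NaN and flagged, not fabricated. AUC is the Mann–Whitney rank statistic
with half-credit ties (vote shares on a finite tree grid do tie), which
equals the trapezoidal area under the empirical ROC. Cutoff sweeps
recompute the full metric row at each grid point; because a child is
predicted "case" iff score ≥ cutoff, sensitivity is non-increasing in the
cutoff.

Prevalence per 1,000 is predicted cases over a population denominator,
with the conventional surveillance 95% CI for a Poisson count,
`rate × exp(±1.96/√cases)`; a zero count gives a flagged degenerate
interval. Concordance profiles report, per prediction×truth cell,
Wilson 95% intervals for categorical attributes and median/IQR for
evaluation counts and age at first evaluation.

## Synthetic corpora

Real surveillance text is confidential, so the generator emulates the
statistical structure the method relies on, with symbolic tokens rather
than clinical prose:

* **Cohorts.** Default 1162 children at the 601/1162 case fraction;
  `addm_like_pair` allocates exactly 601/1162 and 754/1450 for the
  training/test pair, sharing one generative configuration.
* **Evaluations.** Counts per child are shifted negative-binomial per
  class (means 7.9/4.6, dispersion 2.5), targeting medians 7 (cases) vs 4
  (non-cases); age at first evaluation is log-normal targeting medians
  40 vs 53 months; later evaluations follow gamma-distributed gaps.
  Source patterns (school only / health only / both) and
  demographic / prior-diagnosis / secondary-review rates are drawn per
  class from the published concordance strata, pooled within clinician
  class.
* **Text.** Tokens are drawn per evaluation (negative binomial, mean 150,
  dispersion 8) from a mixture of 6,000 Zipf-weighted (exponent 1.05)
  noise terms, identical across classes, and planted discriminative terms
  (default 30 for the ADDM-sized presets, cycling 1/2/3-word phrases
  emitted as contiguous runs) whose usage odds differ between classes by
  `effect_log_odds` (default 2.0). A per-child log-normal multiplier
  (σ = 0.3) on planted-term propensities stands in for within-child
  correlation of evaluation texts; its magnitude is a free parameter, not
  calibrated to real data. All token forms are constructed to be
  stem-stable, so planted term strings coincide with vocabulary terms.
  With these settings the 1162-child corpus yields a post-filter
  vocabulary of roughly 6–7 thousand 1–3-grams — the same order of
  magnitude as real surveillance corpora, whose richer natural language
  reaches the low tens of thousands.

**What the generator does not emulate:** real clinical vocabulary and
syntax, misspellings, negation, template boilerplate shared across
clinics, label noise in the clinician standard, and between-year drift in
terminology. Passing tests on synthetic corpora therefore demonstrate the
mechanics and statistical honesty of the pipeline (signal recovery, OOB
calibration, null safety), not the level of agreement achievable on real
records — synthetic planted signal is cleaner than clinical language, and
end-to-end agreement on the synthetic pair is correspondingly higher than
a real system would see.

**Null corpora.** With zero planted effect but class-conditional
evaluation counts, document *length* still separates the classes — more
evaluations mean more distinct terms, and a bag-of-words forest picks that
up legitimately. A genuine null therefore requires exchangeable classes:
the `null` preset pools all per-class metadata parameters
(`pooled_params`), and only then is test-year AUC ≈ 0.5 the correct
expectation. This is a property of bag-of-words features worth knowing in
production: the classifier partially encodes record volume, not only
language.

## Problem sizes and defaults in tests

Tests and the acceptance script run reduced forests (300 selection / 500
final trees) and moderately sized corpora (300–1450 children, 300–6000
noise terms), which keep every statistical property stable while the full
suite completes in a few minutes; the package defaults remain 10,000/3,000
trees. Hypothesis-based property tests are derandomized.

## Known limitations

* The subset-search rule (smallest k within tolerance of best OOB
  accuracy) is one reasonable formalization of "reduced-feature-set
  model"; alternatives (1-SE rules, forward selection) could pick
  different k on flat accuracy traces.
* Permutation importance dilutes across strongly correlated features
  (e.g. a planted phrase and its component unigrams share importance);
  the top-175 candidate pool is wide enough that this does not affect
  recovery in practice.
* IDF statistics are frozen from the training year when scoring new
  years; refitting IDF on the new year is a defensible alternative and a
  one-line change in `transform_tdm`.
* Prevalence CIs use the Poisson log-normal approximation; exact
  (Clopper–Pearson-type) intervals differ slightly at small counts.
* The forest scores are vote shares, not calibrated probabilities; no
  probability calibration beyond the class-balance cutoff is attempted.
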