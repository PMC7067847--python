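# Methods

## The design

`langshift` implements a case-crossover analysis of language change on
social media before hospital visits.  The case-crossover design compares
each patient's exposure before an event with that same patient's exposure
before a comparison time point, so every patient serves as their own
control and time-invariant between-patient differences (verbosity, topic
preferences, secular posting trends) cancel out.

Two events are defined per patient:

* **true event** — the patient's most recent hospital visit (ED without
  admission, or inpatient; the two arms are analysed separately) whose
  lookback satisfies the inclusion rule;
* **null event** — a random date in the same patient's posting history.

Before each event lies a 75-day lookback: an *earlier* 30-day window, a
15-day gap, and a *recent* 30-day window ending the day before the event
(the event day itself is excluded).  A patient is eligible only when both
windows of an event contain at least `min_posts_per_window` posts; the
default 21 encodes "more than 20 posts per month" as a strict inequality,
with the threshold exposed as a knob.

Per window, the posts are reduced to a named feature vector; *change* is
recent minus earlier within one event, and the *diff-of-diff* is the true
event's change minus the null event's change.  Diff-of-diffs feed two
analyses: per-feature paired inference, and a classifier that predicts
whether a change vector precedes a visit.

### Open design points and how they were resolved

* **Most recent visit failing inclusion.**  It is ambiguous whether such a
  patient is dropped or an earlier visit is used.  The default scans back
  to the most recent *qualifying* visit (maximizing cohort size); a
  `strict` flag keeps only the single most recent visit.
* **Null-event support and overlap.**  The null date is drawn uniformly
  from `[first_post + 75 days, last_post]` so the full lookback exists, and
  by default its 75-day period may not overlap the true event's period —
  overlap would leak case-window language into the control.  A flag allows
  overlap.  Sampling retries up to 200 draws, then drops the patient.
* **Date handling.**  All dates are naive local calendar dates; posts are
  assigned to windows by calendar date with inclusive interval endpoints.
  Date-only timestamps are given 12:00 so they land in a defined clock bin.

## Language features

Four feature groups, each a pure function of the window:

* `dict:<category>` — closed-vocabulary dictionary relative frequencies:
  matched tokens / total tokens in the window.  Patterns are literal words
  or stems with a trailing `*` wildcard (prefix match); a token matching
  several categories counts once in each.
* `topic:<id>` — topic loadings from a pre-fitted topic-word weight table:
  loading(t) = Σ_w freq(w|window)·p(t|w), with p(t|w) the word's weights
  normalized over topics and freq relative to in-vocabulary tokens.  This
  word-level mixture is the standard lexicon-style approximation of
  per-document topic inference; fitting the topic model itself is out of
  scope (the table is an input).
* `lex:<name>` — weighted-lexicon scores: intercept + Σ_w weight(w)·
  freq(w|window), for valence/arousal/anxious/depressed/extraverted-style
  models supplied as word-weight CSVs.
* `meta:*` — posting statistics: posts per half-open 3-hour clock bin
  (eight bins), total posts, mean tokens per post.

Raw 1–3-gram relative frequencies are computed (grams never span post
boundaries) but excluded from the default model matrix behind a flag: the
closed sets above are the analysis features, while open-vocabulary grams
exist mainly as inputs to topic modelling.

The tokenizer is fixed as the package's reference tokenizer because no
canonical specification exists for this kind of corpus: lowercase, URLs
stripped, a fixed emoticon list kept as single tokens, apostrophe
contractions intact, split on remaining punctuation/whitespace.  It is
swappable at the `tokenize` interface.

## Inference

Per feature, the per-patient diff-of-diffs D_i are tested with a classical
two-tailed paired t-test (t = mean(D)/ (sd(D)/√n), p from t with n−1 df),
corrected across features with Benjamini–Hochberg step-up (p·m/rank with a
downward cumulative minimum), and summarized by paired Cohen's d_z =
mean(D)/sd(D) with the normal-approximation CI d ± 1.96·√(1/n + d²/2n).
d_z was chosen among the paired-d variants because its numerator is exactly
the reported mean diff-of-diff; the CI is reported for d (an interval for
the raw mean is also emitted).  Features with zero variance are reported as
non-testable rather than dropped silently, and are excluded from the BH
family.  BH is applied jointly across all feature groups within an
analysis arm (the conservative choice).  These four statistics are
implemented from their definitions and cross-checked in the test suite
against scipy, statsmodels and scikit-learn to 1e-10.

## Forecasting

The model matrix holds two rows per patient (true-event change, label 1;
null-event change, label 0).  Evaluation is k-fold cross-validation with
patient-exclusive folds: patients are shuffled by the run seed and split
into k groups, and both rows of a patient share a fold.  Per fold, features
are standardized and reduced by PCA — both fitted on the training fold only
— keeping the minimal number of components reaching 95% cumulative
explained variance (the retained-variance fraction is configurable; the
standardize-then-PCA order is required because the feature groups have
very different scales).  The classifier is a linear ensemble: the
unweighted mean of the class-1 probabilities of a random forest, a
Platt-scaled SVM, a gradient-boosting classifier, and logistic regression,
all with library-default hyperparameters pinned only by the run seed.  An
L2-penalized logistic regression is run under the identical protocol as an
active control.

Reported metrics: pooled (micro) AUC over out-of-fold scores — computed
from the Mann–Whitney definition with ties counted half, which equals the
trapezoidal ROC area — plus per-fold AUCs and their mean, and F1 at a fixed
0.5 probability threshold on the pooled scores (the thresholding rule is a
package choice; nothing in the design pins it).

## The synthetic cohort generator

Real corpora of this kind cannot be shared, so the generator produces
cohorts with exactly the structure the analysis assumes, plus a known
injected signal:

* per patient, daily post counts ~ Poisson(`posts_per_day_rate`, default
  1.5/day) over `history_days` (default 365, minimum twice the 75-day
  period), with uniform within-day times;
* post lengths ~ Poisson(`words_per_post`, default 12) truncated at ≥1;
* tokens i.i.d. from a background vocabulary of Zipf-weighted filler words
  plus six dictionary categories (health, informal, family, leisure,
  negemo, social) whose baseline emission mass is ≈4–5% each — the range
  typical of closed-vocabulary categories;
* every patient (by default) receives one visit, uniform over the feasible
  tail of the history so the full lookback exists;
* inside the 30 days before the visit (the recent window only, not the
  gap) each configured category's word probabilities are multiplied by its
  effect multiplier and the vocabulary renormalized.

Because tokens are i.i.d. within a window, the window count of a category
with probability p is Binomial(N, p) with N the window's token mass, and
the injected paired effect has the closed form

    d_z = (p1 − p0) / sqrt[(p1(1−p1) + 3·p0(1−p0)) · E[1/N]],

with p1 = m·p0/Z the boosted, renormalized probability and E[1/N]
approximated to second order from the compound-Poisson moments of N.
`expected_effect` evaluates this, `multiplier_for_effect` inverts it by
root-finding, and a brute-force Monte-Carlo simulation of the four-window
diff-of-diff verifies the formula within 10% in the tests.

What the generator deliberately does **not** emulate: grammar and word
order (features are order-insensitive by design; n-grams beyond unigrams
carry no signal), between-patient heterogeneity in rates or vocabulary,
multiple visits per patient, diurnal/weekly posting rhythms, and secular
vocabulary drift.  Passing calibration on synthetic data therefore shows
the machinery is correct and calibrated under the design's assumptions; it
does not certify performance on real social-media corpora, where effect
sizes, dependence structures and eligibility attrition differ.

## Problem sizes and numerical choices

* Null calibration: the AUC band check runs one cohort of 400 patients;
  the realized-FDR check averages 200 independent differential runs of 100
  patients with a 160-day history — BH calibration is sample-size-free in
  expectation, so the smaller per-run cohort buys replication where it
  matters (the Monte-Carlo error of the FDP mean).
* Parameter recovery: 20 seeds × 200 patients at an injected d_z of 0.3.
* Signal grid: injected d_z ∈ {0, 0.25, 0.5, 1.0}, 400 patients, 3 seeds
  per level averaged so adjacent levels are separated by several times the
  seed-to-seed AUC spread.
* All randomness flows through explicit integer seeds (numpy Generators);
  sub-seeds are derived with an auxiliary generator and kept below 2^31.
  Null-event resampling consumes randomness only on the null side, so
  true-event quantities are bit-identical across control-set seeds.
* Run manifests contain only deterministic content (config snapshot,
  seeds, content hashes of inputs and outputs); stage wall-clock timings go
  to the log, so same-seed reruns are byte-identical.
* Degenerate windows (no tokens) yield all-zero dictionary/topic features
  with a defined flag; they cannot occur for eligible patients, who have
  ≥21 posts of ≥1 token per window.

## Known limitations

* Topic loadings are a word-mixture approximation, not posterior inference
  over a fitted topic model.
* The d_z confidence interval uses the normal approximation; a noncentral-t
  interval would be more accurate at small n.
* One visit per patient; time-stratified referent sampling variants of the
  case-crossover design are out of scope.
* The tokenizer's emoticon list is fixed and small; emoji normalization is
  not attempted.
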