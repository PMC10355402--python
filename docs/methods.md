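# Methods

This note documents the models and procedures implemented in
`misinfowatch`, the assumptions they make, the defaults and why, and what a
green test on synthetic data does and does not establish.

## 1. Problem setting

Given a large corpus of vaccine-related posts and their author accounts,
the pipeline (a) assigns every post a binary label — 1 for misinformation,
0 for factual/other content — starting from a small expert-labeled seed,
and (b) characterizes where, when, and by whom misinformation is spread.
Only a tiny fraction of posts can be expert-labeled, which motivates the
two labeling mechanisms below.

## 2. Weak labeling

**Keyword augmentation.** The positive class is rare (~6%), so the seed set
is enriched with weak positives harvested by an include/exclude term query.
Default include terms: `5G, poison, microchip, hoax`; default exclude
terms: `misleading, conspiracy`. The exclusions remove posts that *discuss*
misinformation (fact-checks, warnings) rather than assert it — e.g. a tweet
mocking "conspiracy theorists" that mentions 5G is not itself
misinformation. Matching is case-insensitive on word boundaries that treat
digits as word characters, so `5G` matches `5g` but not `15GB`. Selection
is capped at `target_additions` (default 4,000) in pool order for
reproducibility; a seeded random mode exists. The weak labels are noisy by
construction (the real procedure included a manual review pass we do not
emulate); the classifier and the expert oracle in the active-learning loop
are what correct for this.

**Guideline criteria.** The annotation handbook (unsourced treatment
claims, unsourced blame for vaccine consequences, conspiracy narratives vs.
personal experience, hopes/ads/politics) is shipped as an editable YAML
criteria file with best-effort regex encodings. These are *advisory only*:
they flag candidate labels for human review and never override a manual
label. No claim is made that the patterns reproduce annotator judgment.

**Merging.** Manual labels always win over augmented ones; conflicting
duplicate manual labels are a hard error, duplicate consistent ones are
deduplicated. The merge emits a per-class balance report.

## 3. Classifier and active learning

**Featurization** (deliberately simple, order-insensitive): lowercase word
unigrams + bigrams, minimum document frequency 2, tf-idf weighting with l2
row normalization. The vocabulary is fitted once on the initial labeled set
and frozen, so decision values remain comparable across iterations; refit
per iteration is available via `FeatureSpec(refit_per_iteration=True)`.

**Model.** A linear support-vector classifier trained by minimizing
½‖(w, b)‖² + C Σᵢ max(0, 1 − yᵢ(w·xᵢ + b))² with C = 1.0 (the standard
default for this estimator family), a seeded optimizer, and a fixed
iteration cap. The decision function f(x) = w·x + b is the signed distance
(up to ‖w‖) to the separating hyperplane; the predicted label is 1 iff
f(x) > 0. Training on single-class data raises an error naming the missing
class.

**Uncertainty sampling.** Each iteration selects the
min(batch_size, |pool|) pool items with the smallest |f(x)| under the
current model ("lowest absolute confidence"), queries the oracle, moves
them from pool to training set, retrains, and evaluates. Defaults:
batch_size 100, max_iterations 50 — a 5,000-query labeling budget. Two
readings of "average absolute confidence" are supported:
`uncertainty_mode="single"` (default) uses the current model's |f(x)|;
`"cv_average"` averages |f(x)| over k models trained on CV folds of the
labeled set. Ties in |f(x)| break by ascending tweet id for determinism.
An oracle failure aborts the step with the state unchanged.

**Evaluation.** Default `eval_mode="cv"`: stratified seeded 5-fold
cross-validation on the current labeled set after each iteration,
reporting accuracy, precision, recall, and the F-score (harmonic mean of
precision and recall for the misinformation class). `"holdout"` evaluates
on a fixed labeled holdout instead — much cheaper for long runs — and
`"none"` skips evaluation. A `selection="random"` mode replaces
uncertainty sampling with seeded random batches; it exists solely as the
baseline in sample-efficiency comparisons.

**Invariants** (tested): |labeled| + |pool| is conserved; labeled and pool
stay disjoint; selection equals an exhaustive sort by (|f(x)|, id); on
separable synthetic data the learning curve is non-decreasing within noise
and the largest positive weights recover the planted indicator terms.

## 4. Geographic and temporal summaries

**Gazetteer mapping.** Free-text profile locations are split on commas,
tokenized, and matched longest-term-first against a term→country table
(countries, regions, provinces, cities; case-insensitive). Exactly one
distinct matched country wins; zero or conflicting matches (e.g. "Georgia",
a US state and a country) map to the `UNMAPPED` sentinel. This conservative
policy is auditable: it never guesses. The shipped gazetteer is a small
editable CSV; coverage is a data concern, not code.

**Country summaries.** One row per country with ≥1 tweet; tweets by
unmapped or unknown authors aggregate under `UNMAPPED`. A multi-tweet
user's country counts once per tweet (the summaries are *tweets* per
country). Ratios are exact; rendering is separate: percentages print with
one decimal, half-up (so a ratio of 2111/30358 renders "7.0%").

**Weekly series.** Counts are bucketed by the ISO-8601 week of the tweet's
UTC timestamp, keyed "YYYY-WW" (e.g. "2020-44"); ISO rules decide
year-boundary weeks (2021-01-01 belongs to 2020-53). Interior empty weeks
are zero-filled. Min-max normalization maps a series to [0,1] via
(v − min)/(max − min); a constant series maps to all zeros (a defined
degenerate case, not an error). Peak annotation returns the earliest week
attaining the maximum raw count.

## 5. Account profiling

Demographic attributes arrive as probability vectors per account — age over
{≤18, 19–29, 30–39, ≥40}, gender over {male, female}, organization status
over {org, non-org} — produced by an external multimodal inference service;
bot scores arrive as six categories in [0,1] (overall, astroturf,
fake follower, self-declared, financial, spammer) from an external
bot-detection service. The package never computes either from content:
both are inputs, and only 10% of accounts are assumed profiled by default
(seeded uniform sample), emulating the cost of the external service.

Assignment is per-dimension argmax; exact ties break by a fixed category
order (youngest age, female, org) and are logged. An account belongs to the
misinformation (fact) spreader class iff it authored ≥1 tweet with final
label 1 (0) — the simplest auditable membership rule; dual membership is
allowed and counted. Engagement comparisons report per-class means of
followers/friends/favourites over accounts with data (denominators
reported) and fact/misinformation cross-ratios; bot comparisons report
per-category mean scores over seeded samples of up to 1,000 accounts per
class (all accounts, with a warning, when a class is smaller). The
misinformation age distribution counts tweets by default (content volume);
a per-user mode exists because either reading is defensible.

## 6. The synthetic world

The generator emulates the statistical structure the analysis assumes, not
real tweets. Texts are bag-of-token samples from class-conditional
distributions over a shared background vocabulary plus indicator terms —
sufficient because the featurization is order-insensitive. Defaults, fixed
before any acceptance measurement:

| parameter | default | rationale |
|---|---|---|
| misinformation prevalence | 0.06 | observed share of misinformation posts |
| study window | 2020-W44 … 2021-W21 | the emulated collection period |
| surge weeks (global multiplier) | 2020-51 ×4, 2020-52 ×3, 2021-02 ×1.8, 2021-10 ×2.2 | December emergency-authorization surge; March volume peak |
| indicator-term rate (misinfo / fact texts) | 0.25 / 0.01 | strong but imperfect lexical signal; fact side yields hard negatives |
| followers mean (fact / misinfo) | 1500 / 300 | the reported ~5× follower gap; absolute scale is a modeling choice |
| friends mean (fact / misinfo) | 400 / 500 | misinformation spreaders make ~25% more friends |
| favourites mean (fact / misinfo) | 3000 / 2190 | misinformation spreaders give ~27% fewer favourites |
| verified probability (fact / misinfo) | 0.03 / 0.01 | ~3× fewer verified badges among spreaders |
| astroturf bot-score mean (misinfo / fact) | 0.25 / 0.12 | the reported cross-class contrast |
| other bot categories | overall 0.30/0.20, fake follower 0.20/0.14, self-declared 0.18/0.10, financial ≈, spammer ≈ | elevated overall/self-declared/fake-follower; financial and spammer similar by design |
| misinfo age mixture | (0.20, 0.18, 0.25, 0.37) | ≥40 modal, 19–29 lowest at ~half the ≥40 share |
| tweets per user | mean 3, heavy-tailed (Pareto weights) | multi-tweet authorship; the true distribution is unknown, so this is a flagged modeling choice |
| engagement counts | log-normal (σ = 1) with the above arithmetic means | non-negative, right-skewed |
| bot scores | Beta(μκ, (1−μ)κ), κ = 20 | respects [0,1] support |
| demographic vectors | Dirichlet peaked on the true category (sharpness 12) | argmax usually, not always, recovers the category |
| country mixture | US-dominated English-speaking mix, 38% unmappable free text | English-keyword collection skew; exercises the gazetteer |

Determinism: the same config and seed produce byte-identical tables. Ground
truth is returned separately from the corpus and consumed only by the
simulated oracle and by evaluation code.

**What the generator does not emulate** — and therefore what a green test
does not establish: real linguistic variation (sarcasm, code-switching,
implicit claims), retweet/reply network structure, annotator disagreement,
label noise in the manual seed, platform moderation effects, non-English
content, or correlation between account attributes and text content beyond
class membership. Classifier accuracies on this world are upper bounds with
no bearing on real-data performance; the study-scale metrics of the
emulated analysis are not reproducible here and are not claimed.

## 7. Numerical and design choices

- Percentages: `decimal` half-up rounding to one decimal; "7%" and "7,5%"
  style variants are normalized to "7.0%" / "7.5%".
- Timestamps: timezone-aware UTC; naive inputs assumed UTC.
- Join key: username ↔ screen_name, case-insensitive; duplicate screen
  names are a hard error; tweets without a user record are retained for
  content/temporal analysis but excluded from account profiling.
- min-max of a constant series → all zeros; empty series → error.
- `sample_users` uses round(fraction·n) with a seeded generator.
- Keyword selection cap: pool order (deterministic); seeded random optional.
- The 10% demographic sampling is seeded-uniform; whether the emulated
  procedure sampled randomly is unknown.
- Model persistence is a JSON file (vocabulary, idf, weights, bias,
  hyperparameters); no pickles.

## 8. Known limitations

- The gazetteer is intentionally small (~130 terms); real deployments
  should supply a fuller term table via `Gazetteer.from_csv`.
- The guideline criteria file is a best-effort encoding of rules written
  for humans; its advisory labels are not validated against annotators.
- Weak-positive precision depends on the synthetic hard-negative rate; on
  generator defaults roughly half of keyword-harvested tweets are true
  positives, which is realistic for un-reviewed keyword queries but means
  `labels_training.csv` must not be treated as gold.
- `cv_average` uncertainty is k× the cost of `single` and rarely changes
  the selected batch on separable data.
- The pipeline's predicted prevalence can exceed the true prevalence when
  the weak-label noise is positive-biased (as with the default keyword
  query); downstream ratios inherit that bias.
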