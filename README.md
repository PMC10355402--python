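# misinfowatch

A tested, reusable pipeline for surveilling vaccine misinformation on
Twitter-like corpora. It is aimed at infodemiology / digital public-health
researchers who need to (1) bootstrap a labeled training set from a small
manual seed plus keyword-harvested weak positives, (2) train a
misinformation classifier with pool-based active learning, and (3) profile
how misinformation spreads over time, across countries, and across account
types (demographics, engagement metrics, bot-likeness scores).

Because large tweet collections are proprietary and the external inference
services (demographic inference, bot scoring) cannot be re-run offline, the
package ships a first-class **synthetic corpus generator** whose defaults
encode the statistical structure such a collection exhibits: ~6%
misinformation prevalence, class-discriminative vocabulary, a country
mixture dominated by English-speaking countries, event-driven weekly
surges, class-conditional account engagement, and six-category bot-score
vectors. Every downstream stage is exercised end-to-end against this
stated world.

## The method

**Weak labeling.** A manually annotated seed set (label 1 = misinformation,
0 = fact) is expanded with weak positives selected by a keyword query: a
tweet qualifies iff it contains at least one misinformation-indicator term
("5G", "poison", "microchip", "hoax", …) and no exclusion term
("misleading", "conspiracy" — which mark tweets *warning about*
misinformation). Matching is case-insensitive on word boundaries, so "5G"
matches "5g" but not "15GB". Merging is manual-wins.

**Active learning.** Texts are featurized as tf-idf over lowercase word
unigrams+bigrams (min document frequency 2). A linear support-vector
classifier f(x) = w·x + b is trained on the labeled set; the predicted
class is 1 iff f(x) > 0. At each iteration the batch of B = 100 pool tweets
with the smallest |f(x)| — the samples closest to the separating
hyperplane, i.e. those the model is least certain about — is sent to an
oracle (human expert, or the generator's ground truth), moved into the
training set, and the model is retrained and re-evaluated (stratified
seeded k-fold cross-validation by default, k = 5). The loop stops after 50
iterations or pool exhaustion. Uncertainty ties break by ascending tweet
id, so runs are fully deterministic given a seed.

**Profiling.** Profile locations are normalized to countries with a
gazetteer (longest-match-first; ambiguous or unmatched text maps to
`UNMAPPED`). Per-country misinformation ratios are n₁/n with half-up
percentage rendering; weekly series use ISO-8601 weeks ("2020-44") with
min-max normalization v' = (v − min)/(max − min). Demographic attributes
are assigned per-dimension argmax over externally supplied probability
vectors; spreader classes are compared on verified/gender/org ratios, mean
followers/friends/favourites, and per-category mean bot scores over seeded
1,000-account samples.

## Worked example

```python
import numpy as np
from misinfowatch.synthetic import GeneratorConfig, generate_corpus, make_oracle
from misinfowatch import active_learning as al
from misinfowatch.geo_temporal import country_summaries

corpus, truth = generate_corpus(GeneratorConfig(n_tweets=10_000, seed=7))
texts = dict(zip(corpus.tweets["id"], corpus.tweets["text"]))
ids = corpus.tweets["id"].tolist()
initial = {t: truth[t] for t in ids[:2000]}          # expert-labeled seed
oracle = make_oracle(truth)                          # simulated annotator
state, history = al.run_active_learning(initial, ids[2000:], texts, oracle,
                                        batch_size=100, max_iterations=10,
                                        eval_mode="cv", seed=7)
print(history.tail(3).round(3))
```

prints the cross-validated learning curve (accuracy, precision, recall and
F-score for the misinformation class):

```
 iteration  n_labeled  accuracy  precision  recall  f_score
         8       2800     0.944      0.924   0.614    0.737
         9       2900     0.947      0.937   0.631    0.753
        10       3000     0.952      0.951   0.654    0.772
```

After 10 iterations (1,000 oracle queries) the model labels the full corpus
at 0.998 agreement with ground truth and a predicted prevalence of 5.6%
(true prevalence 5.9%), and its largest positive weights recover the
planted indicator vocabulary:

```
top misinformation terms: ['5g', 'sheeple', 'tracking', 'poison',
                           'bleach', 'zinc', 'magnetic', 'microchip']
```

Country summaries and bot-score comparisons come straight off the labeled
corpus:

```python
corpus = corpus.with_labels(al.predict_corpus(state.featurizer, state.model, corpus))
print(country_summaries(corpus).head(3))
#  country  n_tweets  n_misinformation  misinformation_ratio ratio_percent
# UNMAPPED      4034               184              0.045612          4.6%
#       US      3023               117              0.038703          3.9%
#       UK       985                78              0.079188          7.9%
```

The mean astroturf bot score of misinformation-spreading accounts (0.245)
is roughly twice that of fact-sharing accounts (0.119) on generator
defaults — the planted cross-class contrast.

## Command line

Each stage is a subcommand over a shared working directory, and `run`
executes the whole chain with a reproducibility manifest (file hashes,
seeds, per-stage wall time):

```bash
misinfowatch generate --out runs/demo --seed 7 --n-tweets 20000
misinfowatch augment   --out runs/demo --seed 7
misinfowatch train-al  --out runs/demo --seed 7
misinfowatch classify  --out runs/demo --seed 7
misinfowatch summarize --out runs/demo --seed 7
misinfowatch profile   --out runs/demo --seed 7
# or all at once:
misinfowatch run --out runs/demo --seed 7
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the complete pipeline — synthetic corpus generation, seed labeling
plus keyword augmentation, 50 active-learning iterations at batch size 100,
full-corpus classification, country/weekly summaries, and account
profiling — from scratch under the given seed and writes the results JSON.
Stage outputs land under `scratch/acceptance_run_<seed>/`.

See `docs/methods.md` for the model assumptions, generator design, default
parameters, and known limitations.
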