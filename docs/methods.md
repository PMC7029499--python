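# Methods

This note documents the models and procedures implemented in `vaxstance`,
the choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## The task

Given a stream of short messages mentioning vaccination-related key terms,
flag those whose author holds a *negative stance* towards vaccination.
Stance is not surface sentiment: the annotation scheme codes each message
for relevance (Relevant / Relevant abroad / Irrelevant), subject (Vaccine /
Disease / both), stance (Negative / Neutral / Positive / Not clear) and
sentiment (Informative / Anger-frustration / Worry-fear-doubts / Relieved /
Other), with the sub-categories present only for relevant messages.  Most
messages are coded by two annotators.

## Corpus filtering

Three per-message predicates, applied in collection order for reporting but
order-independent in effect: (1) retweets, detected by a case-insensitive
`RT @` prefix; (2) messages containing a URL, detected by the substrings
`http` or `www.` after lowercasing — a deliberate over-approximation that
catches shortened links without a URL grammar; (3) messages containing a
blacklisted token (`dier`, `landbouw`, `teek`), matched on whole tokens of
the lowercased tokenized text so that e.g. `dierbaar` does not fire.
Filtering is idempotent and the kept set is invariant to rule order.

## Agreement statistics

Three views of coder reliability are computed per categorization:

* **Percent agreement** — share of doubly-annotated units with identical
  labels; units where either coder's value is missing (e.g. stance of an
  Irrelevant message) are excluded.  A flag allows treating missing values
  as an explicit label instead; the default keeps them missing.
* **Krippendorff's alpha**, nominal metric — `1 − Do/De` over the
  coincidence matrix: each unit with `m ≥ 2` values contributes every
  ordered within-unit value pair with weight `1/(m−1)`; `Do` is the
  off-diagonal coincidence mass over the total `n`, `De` the off-diagonal
  mass of the marginals scaled by `n(n−1)`.  Singly-annotated units are
  unpairable and contribute nothing.  When only one distinct label occurs,
  `De = 0` and the implementation raises an explicit undefined-alpha error
  rather than silently returning 1.  The implementation is cross-checked in
  the tests against an independent pair-enumeration oracle on random
  instances.
* **Mutual F-score** — per category, the F1 obtained by treating annotator A
  as ground truth and B as classifier.  Exchanging the roles swaps false
  positives with false negatives while keeping true positives fixed, so the
  score is role-symmetric; the implementation asserts this identity.

A generic category-merge operation supports collapsing confusable
categories (merging Neutral and Not clear raises stance alpha, both on the
published data and on the synthetic corpora).

## Label harmonization

Each tweet becomes one labeled instance with a reliability tier:

* **strict** — both coders assigned the same label,
* **lax** — both coders labeled, but differently; resolved to the more
  preferred label,
* **one** — a single coder.

Agreement is judged at the *finest* labeling level relevant to the scheme
(Polarity for the Binary, IrrelevanceFilter and Polarity schemes;
Polarity+Sentiment for the fourth scheme), then projected down.  This
ordering is what makes the bookkeeping identities hold: the strict Other
count of the Binary scheme equals the sum of the strict non-Negative counts
of the Polarity scheme, because a Positive/Neutral disagreement stays lax
even though both codings project to Other.

The lax preference order at the fine level is Negative > Positive > Neutral
> Not clear > Irrelevant (with the Positive sentiment splits Frustration >
Information > Other slotted in place of Positive for the finest scheme).
Irrelevant is ranked last in every scheme — including the IrrelevanceFilter
scheme, where the preference is Negative > Other > Irrelevant: an
Irrelevant coding never wins a lax resolution, which is why the Irrelevant
count is identical in the strict and strict+lax columns of the published
dataset overview.  Relevant and Relevant-abroad are merged before mapping;
the subject categorization is not used.

Training variants stack tiers: `strict`, `strict+lax`, `strict+one`,
`strict+lax+one`.  The tiers partition the tweet ids, which is what
guarantees test purity during cross-validation.

## Features

The tokenizer is rule-based and Twitter-aware: whitespace chunks survive
whole when they look like a URL, #hashtag, @mention or western-style
emoticon; otherwise leading/trailing punctuation runs are detached as
separate tokens; everything is lowercased.  Features are word uni/bi/
trigrams (joined with `_`, never crossing message boundaries, no padding),
coded binary (present at least once).  The vocabulary is built on training
data only, ranked by document frequency with lexicographic tie-breaking
(the tie rule is a reproducibility choice; the cap itself is 15,000
features by default), and applied per cross-validation fold so held-out
messages can never extend it.

## Classifiers

* **Multinomial naive Bayes** with additive smoothing 0.0 and a muted
  (uniform) class prior.  Literal zero smoothing would take `log 0` on any
  feature unseen in a class; the implementation substitutes an epsilon of
  1e-10 (configurable), which preserves the intended "no smoothing"
  behavior — a single unseen feature effectively vetoes the class — while
  staying numerically defined.
* **Linear SVM** with C = 1.0 and balanced class weights (each class's loss
  contribution scaled by `total/(n_classes · count)`).  The SVM has no
  native probabilities; decision values are mapped through a Platt-style
  sigmoid calibration fitted with 3-fold internal cross-validation on the
  training fold, one-vs-rest for multiclass problems.  Raw one-vs-rest
  decision values remain available as ranking scores.

Both are deterministic given the data and a seed.  Per-message calibrated
probabilities sum to 1; the decided label is the probability argmax unless
a threshold override is applied: the target class is predicted iff its
probability is ≥ the threshold, so threshold 0 flags everything and any
threshold above 1 flags nothing, making recall monotone non-increasing in
the threshold by construction.

## Rule-based sentiment

A lexicon maps tokens to weights in [−1, 1]; an optional modifier table
maps intensifiers to multiplicative factors.  Scanning left to right, a
modifier immediately preceding a weighted token multiplies that token's
weight (clamped) and the pair is consumed as one unit.  The message score
is the **product** of all collected weights, clamped to [−1, 1]; no
weighted tokens means 0.  Product semantics are implemented as specified
even though an even number of negative tokens then scores positive; a
mean-aggregation mode is available behind a flag for experiments where
that pathology matters.  The lexicon is applied to any token, not only
POS-tagged adjectives, since no tagger is in scope.

Calibration of the discrete cut points maximizes Negative-class F1 over a
grid (default 41 evenly spaced cuts in [−1, 1]) for the rule "Negative iff
score ≤ cut"; ties prefer higher precision, then the smaller (more
conservative) cut.  The positive cut is chosen symmetrically when positive
labels are present and the two cuts are reconciled to keep
`negative_cut ≤ positive_cut`.  Discretization is boundary-inclusive.

## Evaluation protocol

All evaluation runs on the strict tier via stratified k-fold
cross-validation (default 10 folds, seeded).  Lax and/or one instances may
augment each fold's training set according to the variant, and never enter
a test fold; disjointness is asserted on every fold.  Confusion counts are
pooled over folds, and the AUC (Mann-Whitney formulation, ties at 1/2) is
computed on the pooled out-of-fold Negative-class probabilities: pooling is
chosen over per-fold averaging because the reference reports present a
single pooled confusion table whose derived metrics match the headline
scores.  Metrics: precision, recall, F1 on the Negative class, with
degenerate denominators reported as 0 with a warning.  Reports round at 2
decimals, half-up.

A class with fewer strict instances than folds raises a stratification
error.  The full grid is 4 labelings × 4 training variants × 2 algorithms
= 32 systems.  Random baselines flag each message Negative with a fixed
rate and score it uniform(0, 1), averaged over seeded repeats.  Ensembles
combine two systems' binary decisions by conjunction (precision-oriented)
or disjunction (recall-oriented) on the Negative vote.  The learning curve
holds out a stratified 10% strict test split once and trains on nested
subsets of the remaining pool (strict + lax by default, configurable)
under one seeded shuffle, skipping single-class subsets with a warning.

## The synthetic corpus generator

The generator exists so every downstream stage is testable without the
original corpus.  Its defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_tweets` | 8259 | size of the annotated set |
| class distribution | strict proportions of the published overview (Negative 343/2886, Positive split 392/300/620, Neutral 345, Not clear 253, Irrelevant 633) | annotation-profile probabilities |
| `single_annotation_rate` | 0.216 | 1787 of 8259 tweets had one coder |
| `agreement_rate` | 0.45 | probability the second coder copies the first (strict fraction 2886/6472) |
| `confusion_model` | 25% true label, 45% confusable partner | deviating stance redraw; Neutral and Not clear mutually confused |
| `relevance_flip_rate` | 0.05 | relevance flips rarely on deviation, so relevance agreement exceeds stance agreement |
| `signal_strength` | 0.2 | fraction of tokens drawn from the class vocabulary ("mid-noise": grid F1 sits mid-range between the random floor and the separability ceiling) |
| artifact rates | retweet 0.31, URL 0.58, blacklist 0.005 | observed per-stage removal fractions |

Tweet text is a bag of 8–25 tokens: with probability `signal_strength`
from a 200-token stance-specific vocabulary, otherwise from a 2,000-token
shared background vocabulary, with **Zipf-distributed** token frequencies
(exponent 1.1).  The heavy tail matters: with small uniform vocabularies,
naive Bayes is exactly the generating model and dominates the SVM,
whereas real tweet text has rare features unseen per class that punish the
zero-smoothing NB — the Zipf tail reproduces that mechanism, and with it
the SVM-over-NB tendency.  One master seed drives everything; each tweet
derives its substream from (seed, index), so earlier tweets are unchanged
when the corpus grows.  A companion lexicon generator assigns negative
weights to the Negative vocabulary and positive weights to the Positive
one so the rule scorer has signal.

What the generator does **not** emulate: real word order and syntax (the
n-gram signal beyond unigrams is incidental), sarcasm and implicit stance,
conversation threads, per-annotator bias (coders are exchangeable), topic
drift over time, and the correlation between message content and whether a
message is a retweet or carries a URL.  Passing the synthetic battery
therefore shows that the machinery is correct and well-calibrated, not
that real-corpus performance would reach the synthetic numbers — on real
Dutch tweets the published Negative-class F1 was 0.36 at AUC 0.66.

## Problem sizes

The test suite and the acceptance script run the heavy experiments at
reduced scale, chosen to keep the full battery in the minutes range while
leaving every statistical check well-powered: the 32-cell grid and the
permutation null on a 1,500-tweet corpus (≈ 800 strict instances) with a
5,000-feature cap, separability and learning-curve checks on 800 tweets
with a 2,000-feature cap, generator marginal checks at 10,000 tweets, and
the Monte-Carlo agreement oracle at 10^6 simulated pairs.

## Known limitations

* Alpha is implemented for the nominal metric only; interval/ordinal
  variants and kappa-family statistics are out of scope.
* The rule scorer's product semantics follow the specification faithfully;
  for lexicon-dense messages the sign-flip pathology makes the mean mode
  preferable in practice.
* More than two annotators per tweet is supported only by alpha (its
  native generalization); percent agreement, mutual F and harmonization
  use the first two coders by sorted annotator id and harmonization
  rejects >2 coders outright.
* The SVM probability calibration method is implementation-defined
  (Platt sigmoid, 3-fold); the reference system did not document its own.
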