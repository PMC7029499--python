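"""Synthetic tweet corpora with paired annotations.

Downstream stages (filtering, agreement, harmonization, classification,
evaluation) are exercised on generated corpora whose controllable knobs
mirror the conditions of the Dutch vaccination-stance annotation study: the
class-profile distribution matches the strict label proportions of the
published dataset overview, roughly 22% of tweets carry a single annotation,
and a doubly-annotated tweet's second coder copies the first's labels with
probability ``agreement_rate``, otherwise deviating (stance redrawn from a
confusion row, sentiment resampled, relevance occasionally flipped — stance
thus disagrees more often than relevance, as observed in the study).

Tweet text is a bag of 8-25 tokens drawn from a stance-specific vocabulary
with probability ``signal_strength`` and from a shared background vocabulary
otherwise, which makes the n-gram classifiers and the lexicon scorer
learnable with tunable difficulty.  Collection artifacts (an ``RT @``
retweet prefix, an ``http`` URL token, animal/travel blacklist words) are
injected at the observed per-stage removal rates so the filter stage has
work to do.

One master seed drives everything; each tweet derives its own substream
from (seed, index), so growing the corpus never reshuffles earlier tweets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .annotation import (
    SENTIMENT_CATEGORIES,
    STANCE_CATEGORIES,
    SUBJECT_CATEGORIES,
    AnnotationProfile,
    AnnotationRecord,
)
from .filtering import Tweet


class ConfigurationError(ValueError):
    """A generator parameter is outside its valid range."""


# -- vocabularies ----------------------------------------------------------

_BACKGROUND_STEMS = (
    "vaccinatie", "prik", "de", "het", "een", "ik", "je", "niet", "wel",
    "over", "voor", "van", "met", "dat", "als", "maar", "ook", "naar",
    "kind", "vandaag",
)

_CLASS_STEMS = {
    "Negative": ("bijwerking", "schade", "gif", "twijfelachtig", "schandalig",
                 "gevaarlijk", "weiger", "onzin"),
    "Positive": ("bescherm", "veilig", "belangrijk", "effectief", "goed",
                 "gezond", "aanrader", "steun"),
    "Neutral": ("vandaag9jarigen", "ggd", "campagne", "programma", "start",
                 "gemeente", "uitnodiging", "ronde"),
    "Not clear": ("vraag", "feiten", "meningen", "discussie", "lastig",
                  "onduidelijk", "beide", "hoezo"),
    "Irrelevant": ("konijn", "kip", "paard", "stal", "kat", "hond", "vogel",
                   "boerderij"),
}

_BLACKLIST_TOKENS = ("dier", "landbouw", "teek")


def class_vocabulary(stance_or_irrelevant: str, size: int = 200) -> List[str]:
    """Deterministic per-class token inventory (disjoint across classes)."""
    stems = _CLASS_STEMS[stance_or_irrelevant]
    return [f"{stems[i % len(stems)]}{i // len(stems)}" for i in range(size)]


def background_vocabulary(size: int = 2000) -> List[str]:
    stems = _BACKGROUND_STEMS
    return [f"{stems[i % len(stems)]}{i // len(stems)}" for i in range(size)]


_ZIPF_EXPONENT = 1.1  # heavy-tailed token frequencies, as in real tweet text


def _zipf_cumulative(size: int) -> np.ndarray:
    weights = 1.0 / np.arange(1, size + 1) ** _ZIPF_EXPONENT
    return np.cumsum(weights / weights.sum())


_ZIPF_CACHE: Dict[int, np.ndarray] = {}


def _zipf_index(rng: np.random.Generator, size: int) -> int:
    cum = _ZIPF_CACHE.get(size)
    if cum is None:
        cum = _ZIPF_CACHE[size] = _zipf_cumulative(size)
    return min(int(np.searchsorted(cum, rng.random(), side="right")), size - 1)


# -- configuration ---------------------------------------------------------

def default_class_distribution() -> Dict[AnnotationProfile, float]:
    """Annotation-profile probabilities matching the published strict label
    proportions (343 Negative, 392/300/620 Positive by sentiment, 345
    Neutral, 253 Not clear, 633 Irrelevant, out of 2,886)."""
    n = 2886.0
    rel = "Relevant"
    return {
        AnnotationProfile(rel, "Vaccine", "Negative", "Anger/frustration"): 137 / n,
        AnnotationProfile(rel, "Vaccine", "Negative", "Worry/fear/doubts"): 137 / n,
        AnnotationProfile(rel, "Disease", "Negative", "Other"): 69 / n,
        AnnotationProfile(rel, "Vaccine", "Positive", "Anger/frustration"): 392 / n,
        AnnotationProfile(rel, "Vaccine", "Positive", "Informative"): 300 / n,
        AnnotationProfile(rel, "Vaccine and disease", "Positive", "Other"): 620 / n,
        AnnotationProfile(rel, "Vaccine", "Neutral", "Informative"): 345 / n,
        AnnotationProfile(rel, "Disease", "Not clear", "Other"): 253 / n,
        AnnotationProfile("Irrelevant"): 633 / n,
    }


def uniform_confusion(labels=STANCE_CATEGORIES) -> Dict[str, Dict[str, float]]:
    """Row-stochastic stance confusion with uniform rows."""
    p = 1.0 / len(labels)
    return {a: {b: p for b in labels} for a in labels}


#: When a second coder deviates, the redrawn stance leans towards the label
#: most often mixed up with the true one: Neutral and Not clear are mutually
#: confused, and stance-bearing labels get diluted towards the unclear ones.
_CONFUSABLE_PARTNER = {
    "Negative": "Not clear",
    "Positive": "Neutral",
    "Neutral": "Not clear",
    "Not clear": "Neutral",
}


def default_confusion(labels=STANCE_CATEGORIES) -> Dict[str, Dict[str, float]]:
    """Deviation model with realistic structure: 25% back to the true label,
    45% to its confusable partner, the rest spread over the other labels."""
    rows: Dict[str, Dict[str, float]] = {}
    for true in labels:
        partner = _CONFUSABLE_PARTNER[true]
        others = [l for l in labels if l not in (true, partner)]
        row = {true: 0.25, partner: 0.45}
        for label in others:
            row[label] = 0.30 / len(others)
        rows[true] = row
    return rows


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus generator; defaults reproduce the
    study's observed conditions (sample size, single-annotation rate,
    artifact rates, class proportions)."""

    n_tweets: int = 8259
    class_distribution: Dict[AnnotationProfile, float] = field(
        default_factory=default_class_distribution
    )
    agreement_rate: float = 0.45
    confusion_model: Dict[str, Dict[str, float]] = field(
        default_factory=default_confusion
    )
    signal_strength: float = 0.2
    retweet_rate: float = 0.31
    url_rate: float = 0.58
    blacklist_rate: float = 0.005
    single_annotation_rate: float = 0.216
    relevance_flip_rate: float = 0.05
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_tweets <= 0:
            raise ConfigurationError("n_tweets must be a positive count")
        total = sum(self.class_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_distribution must sum to 1 (got {total!r})"
            )
        for profile, p in self.class_distribution.items():
            profile.validate()
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"class_distribution probability out of [0,1] for {profile}"
                )
        for row_label, row in self.confusion_model.items():
            row_sum = sum(row.values())
            if abs(row_sum - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"confusion_model row {row_label!r} must sum to 1 (got {row_sum!r})"
                )
            if any(p < 0 for p in row.values()):
                raise ConfigurationError(
                    f"confusion_model row {row_label!r} has a negative probability"
                )
        for name in (
            "agreement_rate",
            "signal_strength",
            "retweet_rate",
            "url_rate",
            "blacklist_rate",
            "single_annotation_rate",
            "relevance_flip_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0,1], got {value!r}")
        return self


@dataclass
class SyntheticCorpus:
    tweets: List[Tweet]
    annotations: List[AnnotationRecord]
    truth: Dict[str, AnnotationProfile]

    def texts(self) -> Dict[str, str]:
        return {tw.id: tw.text for tw in self.tweets}


# -- generation ------------------------------------------------------------

def _tweet_rng(seed: int, index: int) -> np.random.Generator:
    # per-tweet substream: stable under corpus growth
    return np.random.default_rng([seed % (2**31), index])


def _draw(rng: np.random.Generator, items: List, probs: List[float]):
    return items[rng.choice(len(items), p=np.asarray(probs) / np.sum(probs))]


def _stance_key(profile: AnnotationProfile) -> str:
    return profile.stance if profile.stance is not None else "Irrelevant"


def _make_text(
    rng: np.random.Generator, profile: AnnotationProfile, config: GeneratorConfig
) -> str:
    class_vocab = class_vocabulary(_stance_key(profile))
    background = background_vocabulary()
    length = int(rng.integers(8, 26))
    tokens = [
        class_vocab[_zipf_index(rng, len(class_vocab))]
        if rng.random() < config.signal_strength
        else background[_zipf_index(rng, len(background))]
        for _ in range(length)
    ]
    if rng.random() < config.url_rate:
        tokens.insert(int(rng.integers(len(tokens) + 1)), "http")
    if rng.random() < config.blacklist_rate:
        tokens.insert(
            int(rng.integers(len(tokens) + 1)),
            _BLACKLIST_TOKENS[rng.integers(len(_BLACKLIST_TOKENS))],
        )
    text = " ".join(tokens)
    if rng.random() < config.retweet_rate:
        text = f"RT @gebruiker{int(rng.integers(1000))}: {text}"
    return text


def _deviate(
    rng: np.random.Generator, profile: AnnotationProfile, config: GeneratorConfig
) -> AnnotationProfile:
    """Second-coder deviation: flip relevance with small probability, redraw
    stance from the confusion row, resample sentiment uniformly."""
    relevance = profile.relevance
    if rng.random() < config.relevance_flip_rate:
        relevance = "Irrelevant" if relevance != "Irrelevant" else "Relevant"
    if relevance == "Irrelevant":
        return AnnotationProfile("Irrelevant")
    if profile.stance is not None:
        row = config.confusion_model[profile.stance]
        labels = list(row)
        stance = _draw(rng, labels, [row[l] for l in labels])
    else:  # originally Irrelevant, flipped to Relevant
        stance = STANCE_CATEGORIES[rng.integers(len(STANCE_CATEGORIES))]
    sentiment = SENTIMENT_CATEGORIES[rng.integers(len(SENTIMENT_CATEGORIES))]
    subject = SUBJECT_CATEGORIES[rng.integers(len(SUBJECT_CATEGORIES))]
    return AnnotationProfile(relevance, subject, stance, sentiment)


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate ``n_tweets`` tweets with one or two annotations each.

    Deterministic given the config and seed; annotator ids are ``ann1`` and
    ``ann2`` (annotators are treated as exchangeable).
    """
    config.validate()
    profiles = list(config.class_distribution)
    probs = [config.class_distribution[p] for p in profiles]
    cum = np.cumsum(probs)
    tweets: List[Tweet] = []
    annotations: List[AnnotationRecord] = []
    truth: Dict[str, AnnotationProfile] = {}
    for i in range(config.n_tweets):
        rng = _tweet_rng(config.seed, i)
        tweet_id = f"t{i:07d}"
        idx = min(int(np.searchsorted(cum, rng.random(), side="right")), len(profiles) - 1)
        profile = profiles[idx]
        tweets.append(Tweet(tweet_id, _make_text(rng, profile, config)))
        truth[tweet_id] = profile
        annotations.append(
            AnnotationRecord(tweet_id, "ann1", profile.relevance, profile.subject,
                             profile.stance, profile.sentiment)
        )
        if rng.random() >= config.single_annotation_rate:
            second = (
                profile
                if rng.random() < config.agreement_rate
                else _deviate(rng, profile, config)
            )
            annotations.append(
                AnnotationRecord(tweet_id, "ann2", second.relevance, second.subject,
                                 second.stance, second.sentiment)
            )
    return SyntheticCorpus(tweets, annotations, truth)


def generate_lexicon(config: GeneratorConfig, vocab_size: int = 200) -> Dict[str, float]:
    """A polarity lexicon aligned with the generator's class vocabularies.

    Negative-class tokens receive weights in [-1, -0.3], Positive-class
    tokens weights in [0.3, 1], so the rule-based scorer has signal on
    generated text.  Deterministic given the seed; an empty vocabulary
    yields an empty lexicon.
    """
    rng = np.random.default_rng([config.seed % (2**31), 2**30])
    lexicon: Dict[str, float] = {}
    for token in class_vocabulary("Negative", vocab_size):
        lexicon[token] = float(-rng.uniform(0.3, 1.0))
    for token in class_vocabulary("Positive", vocab_size):
        lexicon[token] = float(rng.uniform(0.3, 1.0))
    return lexicon
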