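"""Harmonize paired annotations into labeled datasets.

Each tweet receives a reliability tier and a label under one of four
labeling schemes of increasing granularity:

* ``Binary`` — Negative vs Other (everything else, including irrelevant).
* ``IrrelevanceFilter`` — Negative / Irrelevant / Other.
* ``Polarity`` — Negative / Positive / Neutral / Not clear / Irrelevant.
* ``PolaritySentiment`` — as Polarity, with Positive split by the sentiment
  coding into Positive+Frustration / Positive+Information / Positive+Other.

Tiers: *strict* tweets were coded identically by both annotators, *lax*
tweets were doubly coded with disagreeing labels and resolved by a fixed
category-preference order (Negative first, Irrelevant last), *one* tweets
have a single annotator.  Agreement is judged at the finest labeling level
relevant to the scheme (Polarity, or Polarity+Sentiment for the fourth
scheme) and then projected down, so e.g. a Positive/Neutral disagreement is
lax under every scheme even though both codings project to the same Binary
label Other.  Training variants stack the tiers: strict, strict+lax,
strict+one, strict+lax+one.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .annotation import (
    AnnotationProfile,
    AnnotationRecord,
    ValidationError,
    is_relevant,
)

TIERS = ("strict", "lax", "one")

VARIANT_TIERS: Dict[str, Tuple[str, ...]] = {
    "strict": ("strict",),
    "strict+lax": ("strict", "lax"),
    "strict+one": ("strict", "one"),
    "strict+lax+one": ("strict", "lax", "one"),
}

POSITIVE_SENTIMENT_SPLIT = {
    "Anger/frustration": "Positive+Frustration",
    "Informative": "Positive+Information",
}


def _fine_polarity(profile: AnnotationProfile) -> str:
    profile.validate()
    if not is_relevant(profile.relevance):
        return "Irrelevant"
    if profile.stance is None:
        raise ValidationError("relevant annotation lacks a stance value")
    return profile.stance


def _fine_polarity_sentiment(profile: AnnotationProfile) -> str:
    label = _fine_polarity(profile)
    if label == "Positive":
        return POSITIVE_SENTIMENT_SPLIT.get(profile.sentiment, "Positive+Other")
    return label


_FINE_MAPS: Dict[str, Callable[[AnnotationProfile], str]] = {
    "Polarity": _fine_polarity,
    "PolaritySentiment": _fine_polarity_sentiment,
}


@dataclass(frozen=True)
class LabelScheme:
    """A labeling granularity: preference-ordered labels plus the mapping
    from a full annotation profile to a scheme label."""

    name: str
    labels: Tuple[str, ...]  # preference order, most preferred first
    display_order: Tuple[str, ...]  # row order for count reports
    fine_level: str  # level at which strict/lax agreement is judged
    project: Callable[[str], str]  # fine-level label -> scheme label

    def preference_rank(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(
                f"label {label!r} not in scheme {self.name!r}"
            ) from None


def _project_binary(fine: str) -> str:
    return "Negative" if fine == "Negative" else "Other"


def _project_irrelevance(fine: str) -> str:
    if fine in ("Negative", "Irrelevant"):
        return fine
    return "Other"


_POLARITY_ORDER = ("Negative", "Positive", "Neutral", "Not clear", "Irrelevant")
_POLSENT_ORDER = (
    "Negative",
    "Positive+Frustration",
    "Positive+Information",
    "Positive+Other",
    "Neutral",
    "Not clear",
    "Irrelevant",
)

SCHEMES: Dict[str, LabelScheme] = {
    "Binary": LabelScheme(
        "Binary", ("Negative", "Other"), ("Negative", "Other"), "Polarity", _project_binary
    ),
    "IrrelevanceFilter": LabelScheme(
        "IrrelevanceFilter",
        ("Negative", "Other", "Irrelevant"),
        ("Negative", "Irrelevant", "Other"),
        "Polarity",
        _project_irrelevance,
    ),
    "Polarity": LabelScheme(
        "Polarity", _POLARITY_ORDER, _POLARITY_ORDER, "Polarity", lambda f: f
    ),
    "PolaritySentiment": LabelScheme(
        "PolaritySentiment", _POLSENT_ORDER, _POLSENT_ORDER, "PolaritySentiment", lambda f: f
    ),
}


def get_scheme(name: str) -> LabelScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise ValidationError(f"unknown labeling scheme: {name!r}") from None


@dataclass(frozen=True)
class LabeledInstance:
    tweet_id: str
    label: str
    tier: str


@dataclass
class DatasetVariant:
    name: str
    instances: List[LabeledInstance] = field(default_factory=list)

    def labels(self) -> List[str]:
        return [inst.label for inst in self.instances]

    def tweet_ids(self) -> List[str]:
        return [inst.tweet_id for inst in self.instances]


def map_profile(profile: AnnotationProfile, scheme: LabelScheme) -> str:
    """Scheme label of one annotation profile."""
    return scheme.project(_FINE_MAPS[scheme.fine_level](profile))


def harmonize(
    records: Iterable[AnnotationRecord], scheme: LabelScheme
) -> List[LabeledInstance]:
    """Assign each annotated tweet a tier and a scheme label.

    Doubly-annotated tweets with identical fine-level labels are strict;
    disagreements are lax, resolved to the most preferred of the two
    fine-level labels before projection; singly-annotated tweets are tier
    ``one``.  More than two annotators per tweet is unsupported.
    """
    fine_map = _FINE_MAPS[scheme.fine_level]
    fine_order = SCHEMES[scheme.fine_level].labels
    by_tweet: Dict[str, List[AnnotationRecord]] = defaultdict(list)
    for rec in records:
        by_tweet[rec.tweet_id].append(rec)
    instances: List[LabeledInstance] = []
    for tweet_id, recs in by_tweet.items():
        if len(recs) > 2:
            raise ValidationError(
                f"tweet {tweet_id!r} has {len(recs)} annotators; at most 2 supported"
            )
        fine = [fine_map(r.profile) for r in sorted(recs, key=lambda r: r.annotator_id)]
        if len(fine) == 1:
            instances.append(LabeledInstance(tweet_id, scheme.project(fine[0]), "one"))
        elif fine[0] == fine[1]:
            instances.append(LabeledInstance(tweet_id, scheme.project(fine[0]), "strict"))
        else:
            preferred = min(fine, key=fine_order.index)
            instances.append(LabeledInstance(tweet_id, scheme.project(preferred), "lax"))
    return instances


def build_variant(
    instances: Sequence[LabeledInstance], variant_name: str
) -> DatasetVariant:
    """Stack the tiers named by the variant (strict data always included)."""
    try:
        tiers = VARIANT_TIERS[variant_name]
    except KeyError:
        raise ValidationError(f"unknown variant name: {variant_name!r}") from None
    return DatasetVariant(
        variant_name, [inst for inst in instances if inst.tier in tiers]
    )


def label_counts(
    instances: Sequence[LabeledInstance], scheme: LabelScheme
) -> pd.DataFrame:
    """Per-label counts for every training variant (dataset overview table)."""
    counts = pd.DataFrame(
        0, index=list(scheme.display_order), columns=list(VARIANT_TIERS), dtype=int
    )
    for variant in VARIANT_TIERS:
        for inst in build_variant(instances, variant).instances:
            counts.loc[inst.label, variant] += 1
    counts.index.name = "label"
    return counts
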