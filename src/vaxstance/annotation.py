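"""Core record types and category inventories for the annotation scheme.

A tweet is coded along four categorizations: *relevance* (is the message
about human vaccination at all), *subject* (vaccine vs disease), *stance*
(the author's position towards vaccination) and *sentiment* (the affect the
message conveys).  The latter three are only coded when the message is
relevant.  Most tweets are coded by two annotators; agreement between them
drives the strict/lax/one reliability tiers used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

RELEVANCE_CATEGORIES = ("Relevant", "Relevant abroad", "Irrelevant")
SUBJECT_CATEGORIES = ("Vaccine", "Disease", "Vaccine and disease")
STANCE_CATEGORIES = ("Negative", "Neutral", "Positive", "Not clear")
SENTIMENT_CATEGORIES = (
    "Informative",
    "Anger/frustration",
    "Worry/fear/doubts",
    "Relieved",
    "Other",
)

CATEGORIZATIONS = ("relevance", "subject", "stance", "sentiment")

_CATEGORY_INVENTORY = {
    "relevance": RELEVANCE_CATEGORIES,
    "subject": SUBJECT_CATEGORIES,
    "stance": STANCE_CATEGORIES,
    "sentiment": SENTIMENT_CATEGORIES,
}


class ValidationError(ValueError):
    """An input value violates the annotation scheme."""


class EmptyDataError(ValueError):
    """No eligible units to compute the requested statistic on."""


def is_relevant(relevance: str) -> bool:
    """Relevant and Relevant-abroad messages both count as relevant."""
    return relevance in ("Relevant", "Relevant abroad")


@dataclass(frozen=True)
class AnnotationProfile:
    """One complete coding of a tweet across the four categorizations.

    ``subject``, ``stance`` and ``sentiment`` are ``None`` exactly when the
    message was judged Irrelevant.
    """

    relevance: str
    subject: Optional[str] = None
    stance: Optional[str] = None
    sentiment: Optional[str] = None

    def validate(self) -> "AnnotationProfile":
        if self.relevance not in RELEVANCE_CATEGORIES:
            raise ValidationError(f"unknown relevance value: {self.relevance!r}")
        for field, value, inventory in (
            ("subject", self.subject, SUBJECT_CATEGORIES),
            ("stance", self.stance, STANCE_CATEGORIES),
            ("sentiment", self.sentiment, SENTIMENT_CATEGORIES),
        ):
            if is_relevant(self.relevance):
                if value is not None and value not in inventory:
                    raise ValidationError(f"unknown {field} value: {value!r}")
            elif value is not None:
                raise ValidationError(
                    f"{field} must be absent for an Irrelevant message, got {value!r}"
                )
        return self


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotator's coding of one tweet."""

    tweet_id: str
    annotator_id: str
    relevance: str
    subject: Optional[str] = None
    stance: Optional[str] = None
    sentiment: Optional[str] = None

    @property
    def profile(self) -> AnnotationProfile:
        return AnnotationProfile(
            self.relevance, self.subject, self.stance, self.sentiment
        )

    def get(self, categorization: str) -> Optional[str]:
        if categorization not in CATEGORIZATIONS:
            raise ValidationError(f"unknown categorization: {categorization!r}")
        return getattr(self, categorization)

    def validate(self) -> "AnnotationRecord":
        if not self.tweet_id:
            raise ValidationError("tweet_id must be non-empty")
        if not self.annotator_id:
            raise ValidationError("annotator_id must be non-empty")
        self.profile.validate()
        return self


def category_inventory(categorization: str) -> tuple:
    try:
        return _CATEGORY_INVENTORY[categorization]
    except KeyError:
        raise ValidationError(f"unknown categorization: {categorization!r}") from None


def double_annotation_rate(records) -> float:
    """Fraction of annotated tweets that carry two annotations."""
    per_tweet: dict = {}
    for rec in records:
        per_tweet.setdefault(rec.tweet_id, set()).add(rec.annotator_id)
    if not per_tweet:
        raise EmptyDataError("no annotation records")
    double = sum(1 for anns in per_tweet.values() if len(anns) >= 2)
    return double / len(per_tweet)
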