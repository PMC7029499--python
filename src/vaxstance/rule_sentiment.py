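"""Rule-based polarity scoring with a weighted lexicon.

A message is scored in [-1, 1] from a lexicon of tokens with hand-assigned
polarity weights.  A modifier token immediately preceding a weighted token
(an intensifier like "horribly" in "horribly good") multiplies that token's
weight; the pair is consumed as a single unit.  The message score is the
product of all (modified) weights found, clamped to [-1, 1]; a message with
no weighted tokens scores 0.  The continuous score is translated into the
discrete labels Negative / Neutral / Positive by thresholds tuned on
training data to maximize F1 on the Negative category.

Note the product semantics make an even number of negative-weighted tokens
score positive; a mean-aggregation mode is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import tokenize


def _clamp(x: float) -> float:
    return max(-1.0, min(1.0, x))


@dataclass
class PolarityLexicon:
    """Token polarity weights in [-1, 1] plus multiplicative modifiers."""

    weights: Dict[str, float]
    modifiers: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for token, w in self.weights.items():
            if not -1.0 <= w <= 1.0:
                raise ValueError(f"weight for {token!r} outside [-1, 1]: {w}")
        for token, m in self.modifiers.items():
            if m <= 0:
                raise ValueError(f"modifier factor for {token!r} must be > 0: {m}")


@dataclass(frozen=True)
class DiscreteThresholds:
    """Cut points translating a polarity score into a discrete label."""

    negative_cut: float
    positive_cut: float = 0.0

    def __post_init__(self):
        if self.negative_cut > self.positive_cut:
            raise ValueError(
                f"negative_cut ({self.negative_cut}) must be <= positive_cut "
                f"({self.positive_cut})"
            )


def token_weights(lexicon: PolarityLexicon, tokens: Sequence[str]) -> List[float]:
    """Left-to-right scan collecting (modified, clamped) token weights."""
    weights: List[float] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if (
            tok in lexicon.modifiers
            and i + 1 < len(tokens)
            and tokens[i + 1] in lexicon.weights
        ):
            weights.append(_clamp(lexicon.modifiers[tok] * lexicon.weights[tokens[i + 1]]))
            i += 2  # the modifier+token bigram acts as one unit
        else:
            if tok in lexicon.weights:
                weights.append(lexicon.weights[tok])
            i += 1
    return weights


def score_text(
    lexicon: PolarityLexicon,
    tokens: Sequence[str],
    mode: str = "product",
) -> float:
    """Polarity score of a tokenized (lowercased) message in [-1, 1]."""
    weights = token_weights(lexicon, tokens)
    if not weights:
        return 0.0
    if mode == "product":
        score = 1.0
        for w in weights:
            score *= w
        return _clamp(score)
    if mode == "mean":
        return _clamp(float(np.mean(weights)))
    raise ValueError(f"unknown aggregation mode: {mode!r}")


DEFAULT_GRID: Tuple[float, ...] = tuple(np.linspace(-1.0, 1.0, 41))


def _negative_prf(scores: np.ndarray, is_negative: np.ndarray, cut: float):
    pred = scores <= cut
    tp = int(np.sum(pred & is_negative))
    fp = int(np.sum(pred & ~is_negative))
    fn = int(np.sum(~pred & is_negative))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def calibrate(
    scores: Sequence[float],
    labels: Sequence[str],
    grid: Sequence[float] = DEFAULT_GRID,
    negative_label: str = "Negative",
    positive_label: Optional[str] = "Positive",
) -> DiscreteThresholds:
    """Choose score cut points maximizing per-class F1 on training data.

    ``negative_cut`` maximizes Negative-class F1 for the rule "Negative iff
    score <= cut"; ties prefer higher precision, then the smaller cut.  The
    positive cut is chosen symmetrically (Positive iff score >= cut) when
    positive labels are present, and defaults to 0 otherwise.  Cuts are
    reconciled so negative_cut <= positive_cut.
    """
    if len(grid) == 0:
        raise ValueError("calibration grid must be non-empty")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    is_negative = labels == negative_label
    if not is_negative.any() or is_negative.all():
        raise ValueError(
            "calibration requires at least one Negative and one non-Negative label"
        )

    def best_cut(key):
        best = None
        for cut in grid:
            cand = key(float(cut))
            if best is None or cand > best:
                best = cand
        return best

    # maximize (F1, precision, -cut) lexicographically
    _, _, neg_cut = best_cut(
        lambda c: (
            _negative_prf(scores, is_negative, c)[2],
            _negative_prf(scores, is_negative, c)[0],
            -c,
        )
    )
    neg_cut = -neg_cut

    pos_cut = 0.0
    if positive_label is not None and (labels == positive_label).any():
        is_positive = labels == positive_label
        _, _, pos_key = best_cut(
            lambda c: (
                _negative_prf(-scores, is_positive, -c)[2],
                _negative_prf(-scores, is_positive, -c)[0],
                c,
            )
        )
        pos_cut = pos_key
    pos_cut = max(pos_cut, neg_cut)
    return DiscreteThresholds(negative_cut=neg_cut, positive_cut=pos_cut)


def discretize(score: float, thresholds: DiscreteThresholds) -> str:
    """Negative iff score <= negative_cut (boundary inclusive); Positive iff
    score >= positive_cut; Neutral in between."""
    if score <= thresholds.negative_cut:
        return "Negative"
    if score >= thresholds.positive_cut:
        return "Positive"
    return "Neutral"


class LexiconSentimentClassifier(BaseEstimator, ClassifierMixin):
    """Estimator facade over the rule scorer: fit calibrates the thresholds
    on training texts/labels, predict emits discrete stance labels.

    Parameters
    ----------
    lexicon : PolarityLexicon
    grid : sequence of candidate cuts for calibration
    mode : "product" (default) or "mean" weight aggregation
    """

    def __init__(
        self,
        lexicon: PolarityLexicon,
        grid: Sequence[float] = DEFAULT_GRID,
        mode: str = "product",
    ):
        self.lexicon = lexicon
        self.grid = grid
        self.mode = mode

    def score_texts(self, texts: Iterable[str]) -> np.ndarray:
        return np.array(
            [score_text(self.lexicon, tokenize(t), self.mode) for t in texts]
        )

    def fit(self, texts: Sequence[str], y: Sequence[str]) -> "LexiconSentimentClassifier":
        self.thresholds_ = calibrate(self.score_texts(texts), y, self.grid)
        self.classes_ = np.array(["Negative", "Neutral", "Positive"], dtype=object)
        return self

    def predict(self, texts: Sequence[str]) -> np.ndarray:
        if not hasattr(self, "thresholds_"):
            raise ValueError("LexiconSentimentClassifier is not fitted yet")
        return np.array(
            [discretize(s, self.thresholds_) for s in self.score_texts(texts)],
            dtype=object,
        )
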