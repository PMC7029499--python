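"""Inter-annotator agreement statistics.

Three complementary views of coder reliability are computed per
categorization: raw percent agreement over doubly-annotated units,
Krippendorff's alpha with the nominal difference metric (chance-corrected,
tolerant of singly-annotated units and varying annotator pairs), and
per-category *mutual F-scores* — the F1 obtained by treating one annotator
as ground truth and the other as a classifier, which is invariant under
exchanging the two roles.

Alpha follows the coincidence-matrix formulation: every unit with m >= 2
values contributes each ordered within-unit value pair with weight
1/(m - 1); observed disagreement Do is the off-diagonal coincidence mass
over the total n, expected disagreement De is the off-diagonal mass of the
marginals, and alpha = 1 - Do/De.  Units carrying a single value are
unpairable and contribute nothing.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .annotation import (
    CATEGORIZATIONS,
    AnnotationRecord,
    EmptyDataError,
    ValidationError,
)


class UndefinedAlphaError(ValueError):
    """Alpha is undefined: only one distinct label among pairable values."""


def _values_by_unit(
    records: Iterable[AnnotationRecord],
    categorization: str,
    absent_label: Optional[str] = None,
) -> Dict[str, List[Tuple[str, Optional[str]]]]:
    """Per tweet, the (annotator, value) list sorted by annotator id.

    ``absent_label`` substitutes a concrete label for missing sub-category
    values (e.g. treating the missing stance of an Irrelevant tweet as an
    explicit fifth value); by default missing stays missing.
    """
    if categorization not in CATEGORIZATIONS:
        raise ValidationError(f"unknown categorization: {categorization!r}")
    units: Dict[str, List[Tuple[str, Optional[str]]]] = defaultdict(list)
    for rec in records:
        value = rec.get(categorization)
        if value is None and absent_label is not None:
            value = absent_label
        units[rec.tweet_id].append((rec.annotator_id, value))
    return {uid: sorted(vals) for uid, vals in units.items()}


def _first_pair(values: List[Tuple[str, Optional[str]]]):
    """The first two annotators' values (sorted by annotator id), or None."""
    if len(values) < 2:
        return None
    return values[0][1], values[1][1]


def percent_agreement(
    records: Iterable[AnnotationRecord],
    categorization: str,
    absent_label: Optional[str] = None,
) -> float:
    """Fraction of doubly-annotated units on which both annotators agree.

    Units where either annotator's value is missing are excluded.
    """
    agree = total = 0
    for values in _values_by_unit(records, categorization, absent_label).values():
        pair = _first_pair(values)
        if pair is None or pair[0] is None or pair[1] is None:
            continue
        total += 1
        agree += pair[0] == pair[1]
    if total == 0:
        raise EmptyDataError(
            f"no doubly-annotated units with {categorization!r} present for both annotators"
        )
    return agree / total


def krippendorff_alpha(
    records: Iterable[AnnotationRecord],
    categorization: str,
    absent_label: Optional[str] = None,
) -> float:
    """Nominal-metric Krippendorff's alpha over all pairable values."""
    coincidence: Dict[Tuple[str, str], float] = defaultdict(float)
    n_total = 0.0
    for values in _values_by_unit(records, categorization, absent_label).values():
        present = [v for _, v in values if v is not None]
        m = len(present)
        if m < 2:
            continue
        n_total += m
        for i, vi in enumerate(present):
            for j, vj in enumerate(present):
                if i != j:
                    coincidence[(vi, vj)] += 1.0 / (m - 1)
    if n_total < 2:
        raise EmptyDataError(f"fewer than two pairable {categorization!r} values")
    marginals: Dict[str, float] = defaultdict(float)
    for (vi, _), mass in coincidence.items():
        marginals[vi] += mass
    d_observed = sum(mass for (vi, vj), mass in coincidence.items() if vi != vj) / n_total
    d_expected = sum(
        marginals[c] * marginals[k]
        for c in marginals
        for k in marginals
        if c != k
    ) / (n_total * (n_total - 1.0))
    if d_expected == 0.0:
        raise UndefinedAlphaError(
            "only one distinct label among pairable values; alpha is undefined"
        )
    return 1.0 - d_observed / d_expected


def mutual_f(
    records: Iterable[AnnotationRecord],
    categorization: str,
    absent_label: Optional[str] = None,
) -> Dict[str, float]:
    """Per-category F1 between the two annotators of each unit.

    One annotator plays ground truth, the other classifier; since exchanging
    the roles swaps false positives with false negatives while keeping true
    positives fixed, F1 is role-symmetric (asserted).  Categories never
    assigned by either annotator are absent from the result.
    """
    pairs: List[Tuple[str, str]] = []
    for values in _values_by_unit(records, categorization, absent_label).values():
        pair = _first_pair(values)
        if pair is None or pair[0] is None or pair[1] is None:
            continue
        pairs.append(pair)
    if not pairs:
        raise EmptyDataError(
            f"no doubly-annotated units with {categorization!r} present for both annotators"
        )
    categories = sorted({v for pair in pairs for v in pair})
    scores: Dict[str, float] = {}
    for cat in categories:
        scores[cat] = _pair_f1(pairs, cat)
        swapped = _pair_f1([(b, a) for a, b in pairs], cat)
        assert abs(scores[cat] - swapped) < 1e-12, "mutual F must be role-symmetric"
    return scores


def _pair_f1(pairs: Sequence[Tuple[str, str]], category: str) -> float:
    tp = sum(1 for a, b in pairs if a == category and b == category)
    fp = sum(1 for a, b in pairs if a != category and b == category)
    fn = sum(1 for a, b in pairs if a == category and b != category)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def merge_labels(
    records: Iterable[AnnotationRecord],
    categorization: str,
    mapping: Mapping[str, str],
) -> List[AnnotationRecord]:
    """Relabel a categorization by merging categories (e.g. Neutral into
    Not clear) and return new records; values not in ``mapping`` pass
    through unchanged."""
    if categorization not in CATEGORIZATIONS:
        raise ValidationError(f"unknown categorization: {categorization!r}")
    merged = []
    for rec in records:
        value = rec.get(categorization)
        if value is not None and value in mapping:
            kwargs = {
                "tweet_id": rec.tweet_id,
                "annotator_id": rec.annotator_id,
                "relevance": rec.relevance,
                "subject": rec.subject,
                "stance": rec.stance,
                "sentiment": rec.sentiment,
            }
            kwargs[categorization] = mapping[value]
            rec = AnnotationRecord(**kwargs)
        merged.append(rec)
    return merged


@dataclass
class AgreementReport:
    """Percent agreement, alpha and mutual F per categorization."""

    percent_agreement: Dict[str, float]
    alpha: Dict[str, float]
    mutual_f: Dict[str, Dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        cats = list(self.percent_agreement)
        return pd.DataFrame(
            {
                "percent_agreement": [self.percent_agreement[c] for c in cats],
                "alpha": [self.alpha[c] for c in cats],
            },
            index=cats,
        )


def agreement_report(
    records: Sequence[AnnotationRecord],
    categorizations: Sequence[str] = CATEGORIZATIONS,
    absent_label: Optional[str] = None,
) -> AgreementReport:
    """All three agreement statistics for each requested categorization."""
    return AgreementReport(
        percent_agreement={
            c: percent_agreement(records, c, absent_label) for c in categorizations
        },
        alpha={c: krippendorff_alpha(records, c, absent_label) for c in categorizations},
        mutual_f={c: mutual_f(records, c, absent_label) for c in categorizations},
    )
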