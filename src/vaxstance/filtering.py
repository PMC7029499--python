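"""Corpus cleaning: retweet, URL and blacklist-word filters.

The monitoring pipeline keeps only original messages plausibly expressing
the sender's own stance: retweets are dropped (duplicated content), messages
containing a URL are dropped (mostly shared news headlines, which do not
reflect the sender's stance), and messages mentioning animal- or
travel-vaccination vocabulary are dropped (out of scope for the national
immunization programme).  Each filter is a per-tweet predicate, so the kept
set does not depend on the order of application; the per-stage counts are
reported in the collection order above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .features import tokenize

STAGE_COLUMNS = ["before", "after_retweets", "after_urls", "after_blacklist"]


@dataclass(frozen=True)
class Tweet:
    """One short message; ``query_term`` records which key term matched it."""

    id: str
    text: str
    query_term: Optional[str] = None


def is_retweet(text: str) -> bool:
    """Classic-style retweets start with an ``RT @user`` marker."""
    return text.lstrip().lower().startswith("rt @")


def has_url(text: str) -> bool:
    lowered = text.lower()
    return "http" in lowered or "www." in lowered


def has_blacklisted_token(text: str, blacklist: Set[str]) -> bool:
    """Whole-token match on the lowercased tokenized text, not substrings."""
    if not blacklist:
        return False
    return any(tok in blacklist for tok in tokenize(text))


def filter_corpus(
    tweets: Sequence[Tweet], blacklist: Iterable[str] = ()
) -> Tuple[List[Tweet], pd.DataFrame]:
    """Apply the three filters in order; return survivors and a stage report.

    The report has one row per query term plus a ``Total`` row, with counts
    before filtering and after each successive stage.  Order of surviving
    tweets is preserved.  Duplicate tweet ids are rejected.
    """
    blacklist = {w.lower() for w in blacklist}
    seen_ids: Set[str] = set()
    for tw in tweets:
        if not tw.id:
            raise ValueError("tweet id must be non-empty")
        if tw.id in seen_ids:
            raise ValueError(f"duplicate tweet id: {tw.id!r}")
        seen_ids.add(tw.id)

    stages = {col: [] for col in STAGE_COLUMNS}
    survivors_by_stage: List[List[Tweet]] = [list(tweets)]
    survivors = list(tweets)
    for predicate in (
        lambda tw: is_retweet(tw.text),
        lambda tw: has_url(tw.text),
        lambda tw: has_blacklisted_token(tw.text, blacklist),
    ):
        survivors = [tw for tw in survivors if not predicate(tw)]
        survivors_by_stage.append(survivors)

    terms = sorted({tw.query_term or "(all)" for tw in tweets}) or ["(all)"]
    rows = {}
    for term in terms:
        rows[term] = [
            sum(1 for tw in stage if (tw.query_term or "(all)") == term)
            for stage in survivors_by_stage
        ]
    rows["Total"] = [len(stage) for stage in survivors_by_stage]
    report = pd.DataFrame.from_dict(rows, orient="index", columns=STAGE_COLUMNS)
    report.index.name = "query_term"
    return survivors, report


def removal_fraction(before: int, after: int) -> float:
    """Fraction of messages removed between two stages."""
    if before <= 0:
        raise ValueError("'before' count must be positive")
    if after > before or after < 0:
        raise ValueError("'after' must lie in [0, before]")
    return (before - after) / before
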