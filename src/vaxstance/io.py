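"""Plain-text persistence: JSON-lines tweets, CSV annotations, TSV lexica."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import pandas as pd

from .annotation import AnnotationRecord
from .filtering import Tweet
from .harmonization import LabeledInstance

ANNOTATION_COLUMNS = [
    "tweet_id", "annotator_id", "relevance", "subject", "stance", "sentiment",
]


def write_tweets(tweets: Iterable[Tweet], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for tw in tweets:
            record = {"id": tw.id, "text": tw.text}
            if tw.query_term is not None:
                record["query_term"] = tw.query_term
            handle.write(json.dumps(record, ensure_ascii=False) + "\n")


def read_tweets(path) -> List[Tweet]:
    tweets = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            record = json.loads(line)
            tweets.append(
                Tweet(str(record["id"]), record["text"], record.get("query_term"))
            )
    return tweets


def write_annotations(records: Iterable[AnnotationRecord], path) -> None:
    frame = pd.DataFrame(
        [
            (r.tweet_id, r.annotator_id, r.relevance, r.subject, r.stance, r.sentiment)
            for r in records
        ],
        columns=ANNOTATION_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_annotations(path) -> List[AnnotationRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            AnnotationRecord(
                tweet_id=row.tweet_id,
                annotator_id=row.annotator_id,
                relevance=row.relevance,
                subject=row.subject or None,
                stance=row.stance or None,
                sentiment=row.sentiment or None,
            ).validate()
        )
    return records


def write_instances(instances: Iterable[LabeledInstance], path) -> None:
    pd.DataFrame(
        [(i.tweet_id, i.label, i.tier) for i in instances],
        columns=["tweet_id", "label", "tier"],
    ).to_csv(path, index=False)


def write_lexicon(lexicon: Dict[str, float], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for token in sorted(lexicon):
            handle.write(f"{token}\t{lexicon[token]}\n")


def read_lexicon(path) -> Dict[str, float]:
    lexicon: Dict[str, float] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            token, weight = line.split("\t")
            lexicon[token] = float(weight)
    return lexicon


def write_vocabulary(feature_names: Sequence[str], document_frequency, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("feature\tdocument_frequency\trank\n")
        for rank, (feat, df) in enumerate(zip(feature_names, document_frequency), 1):
            handle.write(f"{feat}\t{int(df)}\t{rank}\n")
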