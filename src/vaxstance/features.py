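"""Tokenization and binary word-n-gram features for short messages.

Tokenization is rule-based and Twitter-aware: hashtags, user mentions, URLs
and common emoticons survive as single tokens; other punctuation runs are
detached from word tokens; everything is lowercased.  Features are word
uni/bi/trigrams, coded binary (present at least once in the message), over a
vocabulary capped at the most document-frequent n-grams of the training
corpus.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Iterable, List, Sequence

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

NGRAM_JOINER = "_"

# Tokens kept whole: URLs, hashtags, mentions, western-style emoticons.
_URL_RE = re.compile(r"^(https?://\S+|www\.\S+|http\S*)$", re.IGNORECASE)
_HASHTAG_RE = re.compile(r"^#\w[\w-]*$", re.UNICODE)
_MENTION_RE = re.compile(r"^@\w[\w-]*$", re.UNICODE)
_EMOTICON_RE = re.compile(r"^(?:[:;=8xX][\-o^']?[()\[\]dDpP/\\|*sS3cC<>{}]+|<3|</3|\^\^|[()\[\]dDpP/\\|*][\-o^']?[:;=8])$")

_PUNCT = set("!\"#$%&'()*+,-./:;<=>?[\\]^`{|}~«»…‘’“”")


def _is_atomic(token: str) -> bool:
    return bool(
        _URL_RE.match(token)
        or _HASHTAG_RE.match(token)
        or _MENTION_RE.match(token)
        or _EMOTICON_RE.match(token)
    )


def tokenize(text: str) -> List[str]:
    """Split a message into lowercase tokens.

    Whitespace-separated chunks are kept whole when they look like a URL,
    hashtag, mention or emoticon; otherwise leading and trailing punctuation
    runs are split off as separate tokens.  Empty input yields an empty list.
    """
    tokens: List[str] = []
    for chunk in text.split():
        chunk = chunk.strip()
        if not chunk:
            continue
        if _is_atomic(chunk):
            tokens.append(chunk.lower())
            continue
        # peel leading punctuation
        start = 0
        while start < len(chunk) and chunk[start] in _PUNCT:
            start += 1
        end = len(chunk)
        while end > start and chunk[end - 1] in _PUNCT:
            end -= 1
        lead, core, trail = chunk[:start], chunk[start:end], chunk[end:]
        if core and _is_atomic(lead + core + trail):
            # e.g. ":-)" fully punctuation but emoticon-shaped
            tokens.append((lead + core + trail).lower())
            continue
        for run in _punct_runs(lead):
            tokens.append(run)
        if core:
            tokens.append(core.lower())
        elif lead == "" and trail == "":
            # chunk was pure punctuation consumed as lead
            pass
        for run in _punct_runs(trail):
            tokens.append(run)
    return tokens


def _punct_runs(s: str) -> List[str]:
    """Group a punctuation string into runs of identical characters."""
    runs: List[str] = []
    for ch in s:
        if runs and runs[-1][0] == ch:
            runs[-1] += ch
        else:
            runs.append(ch)
    return runs


def extract_ngrams(tokens: Sequence[str], orders: Sequence[int] = (1, 2, 3)) -> List[str]:
    """All word n-grams of the given orders, joined with ``_``.

    N-grams never cross message boundaries and no padding is used.
    """
    grams: List[str] = []
    for n in orders:
        for i in range(len(tokens) - n + 1):
            grams.append(NGRAM_JOINER.join(tokens[i : i + n]))
    return grams


class NgramVectorizer(BaseEstimator, TransformerMixin):
    """Binary presence indicators over a capped word-n-gram vocabulary.

    Candidate features are all uni/bi/trigrams of the training messages,
    ranked by document frequency (number of messages containing the n-gram)
    descending, ties broken lexicographically, and capped at ``max_features``.
    Transform marks each vocabulary n-gram 1 if it occurs at least once in
    the message; out-of-vocabulary n-grams are ignored, so held-out data can
    never extend the vocabulary.

    Parameters
    ----------
    max_features : int, default 15_000
        Vocabulary cap; only the most document-frequent n-grams are kept.
    ngram_orders : tuple of int, default (1, 2, 3)
        Which n-gram orders to extract.

    Attributes
    ----------
    vocabulary_ : dict mapping feature string -> column index
    feature_names_ : list of feature strings in column order
    document_frequency_ : np.ndarray of per-feature document frequencies
    """

    def __init__(self, max_features: int = 15_000, ngram_orders=(1, 2, 3)):
        self.max_features = max_features
        self.ngram_orders = ngram_orders

    @staticmethod
    def _as_tokens(doc) -> List[str]:
        return tokenize(doc) if isinstance(doc, str) else list(doc)

    def fit(self, X: Iterable, y=None) -> "NgramVectorizer":
        """Build the vocabulary from the training messages only."""
        if self.max_features <= 0:
            raise ValueError("max_features must be positive")
        docs = list(X)
        if not docs:
            raise ValueError("cannot build a vocabulary from an empty corpus")
        df: Counter = Counter()
        for doc in docs:
            df.update(set(extract_ngrams(self._as_tokens(doc), self.ngram_orders)))
        # rank: document frequency descending, lexicographic at ties
        ranked = sorted(df.items(), key=lambda kv: (-kv[1], kv[0]))
        kept = ranked[: self.max_features]
        self.feature_names_ = [feat for feat, _ in kept]
        self.document_frequency_ = np.array([c for _, c in kept], dtype=np.int64)
        self.vocabulary_ = {feat: i for i, feat in enumerate(self.feature_names_)}
        return self

    def transform(self, X: Iterable) -> sparse.csr_matrix:
        """Binary feature matrix; repeated n-grams still code 1."""
        check_is_fitted(self, "vocabulary_")
        indptr = [0]
        indices: List[int] = []
        for doc in X:
            seen = {
                self.vocabulary_[g]
                for g in extract_ngrams(self._as_tokens(doc), self.ngram_orders)
                if g in self.vocabulary_
            }
            indices.extend(sorted(seen))
            indptr.append(len(indices))
        data = np.ones(len(indices), dtype=np.float64)
        return sparse.csr_matrix(
            (data, indices, indptr), shape=(len(indptr) - 1, len(self.feature_names_))
        )

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "vocabulary_")
        return np.asarray(self.feature_names_, dtype=object)
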