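"""Published summary statistics of the Dutch vaccination-stance tweet corpus.

The original corpus is Dutch Twitter messages (January 2012 - February 2017)
matching seven vaccination-related query terms, filtered for retweets, URLs
and animal/travel vocabulary, then doubly annotated for relevance, subject,
stance and sentiment.  The raw messages cannot ship with this package; the
study's printed summary tables can, and they serve as fixed inputs for
bookkeeping checks and for reconstructing the published operating points.
All numbers are transcribed from the study's published tables.
"""

from __future__ import annotations

import pandas as pd

#: Query-term filtering counts: messages before filtering, after retweet
#: removal, after URL removal, after blacklist-word removal.
FILTERING_COUNTS = pd.DataFrame(
    [
        ("vaccinatie", 30_730, 20_677, 8_872, 8_818),
        ("vaccin", 21_614, 16_046, 4_154, 4_121),
        ("vaccineren", 20_689, 11_904, 4_682, 4_653),
        ("rijksvaccinatieprogramma", 1_151, 520, 160, 158),
        ("vaccinatieprogramma", 644, 407, 121, 120),
        ("inenting", 8_597, 7_093, 4_046, 4_038),
        ("inenten", 13_141, 9_535, 5_640, 5_626),
    ],
    columns=["query_term", "before", "after_retweets", "after_urls", "after_blacklist"],
).set_index("query_term")

#: Blacklist of animal/travel words used in the third filtering step.
BLACKLIST_WORDS = frozenset({"dier", "landbouw", "teek"})

#: Annotation effort: total annotated tweets and how many were coded twice.
TOTAL_ANNOTATED = 8_259
DOUBLY_ANNOTATED = 6_472

#: Published agreement scores per categorization.
AGREEMENT_SCORES = pd.DataFrame(
    {
        "percent_agreement": [0.71, 0.70, 0.54, 0.54],
        "alpha": [0.27, 0.29, 0.35, 0.34],
    },
    index=["relevance", "subject", "stance", "sentiment"],
)

#: Label counts per labeling scheme and training-data variant (strict /
#: strict+lax / strict+one / strict+lax+one).
LABEL_COUNTS = {
    "Binary": pd.DataFrame(
        {
            "strict": [343, 2_543],
            "strict+lax": [1_188, 5_358],
            "strict+one": [534, 4_074],
            "strict+lax+one": [1_379, 6_889],
        },
        index=["Negative", "Other"],
    ),
    "IrrelevanceFilter": pd.DataFrame(
        {
            "strict": [343, 633, 1_910],
            "strict+lax": [1_188, 633, 4_725],
            "strict+one": [534, 1_077, 2_997],
            "strict+lax+one": [1_379, 1_077, 5_812],
        },
        index=["Negative", "Irrelevant", "Other"],
    ),
    "Polarity": pd.DataFrame(
        {
            "strict": [343, 1_312, 345, 253, 633],
            "strict+lax": [1_188, 2_693, 1_271, 761, 633],
            "strict+one": [534, 1_835, 623, 539, 1_077],
            "strict+lax+one": [1_379, 3_216, 1_549, 1_047, 1_077],
        },
        index=["Negative", "Positive", "Neutral", "Not clear", "Irrelevant"],
    ),
    "PolaritySentiment": pd.DataFrame(
        {
            "strict": [343, 392, 300, 620, 345, 253, 633],
            "strict+lax": [1_188, 726, 1_084, 879, 1_271, 761, 633],
            "strict+one": [534, 560, 513, 762, 623, 539, 1_077],
            "strict+lax+one": [1_379, 894, 1_297, 1_021, 1_549, 1_047, 1_077],
        },
        index=[
            "Negative",
            "Positive+Frustration",
            "Positive+Information",
            "Positive+Other",
            "Neutral",
            "Not clear",
            "Irrelevant",
        ],
    ),
}

#: Binary confusion counts of the best published classifier (SVM, Polarity
#: labeling, strict+lax training) evaluated on the strict data.
BEST_SYSTEM_CONFUSION = {"tp": 161, "fp": 403, "fn": 182, "tn": 2_104}

#: Published precision/recall operating points on the Negative class.
OPERATING_POINTS = {
    "best_ml": (0.29, 0.47),
    "high_recall_threshold": (0.21, 0.60),
    "ensemble_recall": (0.18, 0.61),
}
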