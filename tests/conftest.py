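import pytest

from vaxstance.annotation import AnnotationRecord
from vaxstance.synthetic import GeneratorConfig, generate_corpus


def stance_pair_records(pairs):
    """Doubly-annotated stance records from a list of (ann1, ann2) labels."""
    records = []
    for i, (a, b) in enumerate(pairs):
        tid = f"u{i}"
        records.append(AnnotationRecord(tid, "ann1", "Relevant", "Vaccine", a, "Other"))
        records.append(AnnotationRecord(tid, "ann2", "Relevant", "Vaccine", b, "Other"))
    return records


@pytest.fixture(scope="session")
def clean_config():
    """Study-like conditions but without collection artifacts, as in the
    post-filtering experimentation dataset."""
    return GeneratorConfig(
        n_tweets=1500, seed=5, retweet_rate=0.0, url_rate=0.0, blacklist_rate=0.0
    )


@pytest.fixture(scope="session")
def midnoise_corpus(clean_config):
    return generate_corpus(clean_config)


@pytest.fixture(scope="session")
def separable_config():
    """Fully separable text, perfect agreement, everything double-coded."""
    return GeneratorConfig(
        n_tweets=800,
        signal_strength=1.0,
        agreement_rate=1.0,
        single_annotation_rate=0.0,
        retweet_rate=0.0,
        url_rate=0.0,
        blacklist_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def separable_corpus(separable_config):
    return generate_corpus(separable_config)
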