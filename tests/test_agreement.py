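"""Agreement statistics: percent agreement, nominal alpha, mutual F."""

import random

import pytest

from vaxstance.annotation import AnnotationRecord, EmptyDataError
from vaxstance.agreement import (
    UndefinedAlphaError,
    agreement_report,
    krippendorff_alpha,
    merge_labels,
    mutual_f,
    percent_agreement,
)
from vaxstance.synthetic import GeneratorConfig, generate_corpus

from conftest import stance_pair_records


def brute_force_alpha(units):
    """Independent nominal-alpha oracle: enumerate every ordered within-unit
    value pair explicitly (weight 1/(m-1)) and apply 1 - Do/De."""
    pairs = {}
    n = 0.0
    for values in units:
        values = [v for v in values if v is not None]
        m = len(values)
        if m < 2:
            continue
        n += m
        for i in range(m):
            for j in range(m):
                if i != j:
                    key = (values[i], values[j])
                    pairs[key] = pairs.get(key, 0.0) + 1.0 / (m - 1)
    marg = {}
    for (a, _), w in pairs.items():
        marg[a] = marg.get(a, 0.0) + w
    do = sum(w for (a, b), w in pairs.items() if a != b) / n
    de = sum(marg[a] * marg[b] for a in marg for b in marg if a != b) / (n * (n - 1))
    return 1.0 - do / de


class TestPercentAgreement:
    def test_identical_annotations_give_one(self):
        records = stance_pair_records([("Negative", "Negative")] * 10)
        assert percent_agreement(records, "stance") == 1.0

    def test_three_of_four_agree(self):
        records = stance_pair_records(
            [("Negative", "Negative"), ("Negative", "Positive"),
             ("Positive", "Positive"), ("Positive", "Positive")]
        )
        assert percent_agreement(records, "stance") == pytest.approx(0.75)

    def test_units_with_missing_values_excluded(self):
        records = stance_pair_records([("Negative", "Negative"), ("Positive", "Positive")])
        # an Irrelevant coding carries no stance: that unit must not count
        records.append(AnnotationRecord("x", "ann1", "Relevant", "Vaccine", "Negative", "Other"))
        records.append(AnnotationRecord("x", "ann2", "Irrelevant"))
        assert percent_agreement(records, "stance") == 1.0

    def test_no_eligible_units_is_an_error(self):
        records = [AnnotationRecord("a", "ann1", "Relevant", "Vaccine", "Negative", "Other")]
        with pytest.raises(EmptyDataError):
            percent_agreement(records, "stance")

    def test_annotator_model_expectation(self):
        """agreement_rate a with uniform 2-label deviations agrees at
        a + (1-a)/2 = 0.75 for a = 0.5 (analytic expectation)."""
        dist = {}
        from vaxstance.annotation import AnnotationProfile
        dist[AnnotationProfile("Relevant", "Vaccine", "Negative", "Other")] = 0.5
        dist[AnnotationProfile("Relevant", "Vaccine", "Positive", "Other")] = 0.5
        config = GeneratorConfig(
            n_tweets=10_000,
            class_distribution=dist,
            agreement_rate=0.5,
            confusion_model={s: {"Negative": 0.5, "Positive": 0.5}
                             for s in ("Negative", "Neutral", "Positive", "Not clear")},
            single_annotation_rate=0.0,
            relevance_flip_rate=0.0,
            retweet_rate=0.0, url_rate=0.0, blacklist_rate=0.0,
            seed=21,
        )
        corpus = generate_corpus(config)
        assert percent_agreement(corpus.annotations, "stance") == pytest.approx(0.75, abs=0.02)


class TestKrippendorffAlpha:
    def test_perfect_agreement_is_one(self):
        records = stance_pair_records([("Negative", "Negative"), ("Positive", "Positive")])
        assert krippendorff_alpha(records, "stance") == pytest.approx(1.0)

    def test_hand_computed_coincidence_value(self):
        # pairs (a,a),(a,b),(b,b),(b,b): Do = 2/8, De = 30/56, alpha = 8/15
        records = stance_pair_records(
            [("Negative", "Negative"), ("Negative", "Positive"),
             ("Positive", "Positive"), ("Positive", "Positive")]
        )
        assert krippendorff_alpha(records, "stance") == pytest.approx(
            1 - (2 / 8) / (30 / 56), abs=1e-12
        )

    def test_singly_annotated_units_contribute_nothing(self):
        records = stance_pair_records(
            [("Negative", "Negative"), ("Negative", "Positive"),
             ("Positive", "Positive"), ("Positive", "Positive")]
        )
        before = krippendorff_alpha(records, "stance")
        records.append(
            AnnotationRecord("solo", "ann1", "Relevant", "Vaccine", "Neutral", "Other")
        )
        assert krippendorff_alpha(records, "stance") == pytest.approx(before, abs=1e-12)

    def test_single_label_alpha_is_undefined(self):
        records = stance_pair_records([("Negative", "Negative")] * 4)
        with pytest.raises(UndefinedAlphaError):
            krippendorff_alpha(records, "stance")

    def test_matches_brute_force_oracle_on_random_instances(self):
        labels = ["Negative", "Neutral", "Positive", "Not clear"]
        rng = random.Random(42)
        checked = 0
        while checked < 50:
            pairs = [
                (rng.choice(labels), rng.choice(labels))
                for _ in range(rng.randint(4, 30))
            ]
            units = [list(p) for p in pairs]
            if len({v for unit in units for v in unit}) < 2:
                continue
            if all(a == b for a, b in pairs):
                continue  # Do = 0 handled elsewhere
            records = stance_pair_records(pairs)
            assert krippendorff_alpha(records, "stance") == pytest.approx(
                brute_force_alpha(units), abs=1e-12
            )
            checked += 1

    def test_permutation_invariance(self):
        pairs = [("Negative", "Positive"), ("Positive", "Positive"),
                 ("Neutral", "Neutral"), ("Negative", "Negative")]
        a1 = krippendorff_alpha(stance_pair_records(pairs), "stance")
        a2 = krippendorff_alpha(stance_pair_records(pairs[::-1]), "stance")
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestMutualF:
    def test_identical_annotations_score_one(self):
        records = stance_pair_records([("Negative", "Negative"), ("Positive", "Positive")])
        scores = mutual_f(records, "stance")
        assert scores == {"Negative": 1.0, "Positive": 1.0}

    def test_tp_fp_fn_counting(self):
        # A = [Neg, Neg, Pos], B = [Neg, Pos, Pos] -> F(Neg)=2/3, F(Pos)=2/3
        records = stance_pair_records(
            [("Negative", "Negative"), ("Negative", "Positive"), ("Positive", "Positive")]
        )
        scores = mutual_f(records, "stance")
        assert scores["Negative"] == pytest.approx(2 / 3)
        assert scores["Positive"] == pytest.approx(2 / 3)

    def test_role_symmetry(self):
        pairs = [("Negative", "Positive"), ("Neutral", "Negative"),
                 ("Positive", "Positive"), ("Not clear", "Neutral")]
        direct = mutual_f(stance_pair_records(pairs), "stance")
        swapped = mutual_f(stance_pair_records([(b, a) for a, b in pairs]), "stance")
        assert direct == pytest.approx(swapped)

    def test_absent_category_not_reported(self):
        records = stance_pair_records([("Negative", "Positive")])
        assert "Neutral" not in mutual_f(records, "stance")

    def test_frequent_categories_score_higher_on_synthetic_data(self, midnoise_corpus):
        """With frequency-proportional agreement, the dominant category gets
        the best mutual F (the tendency seen in double-coded stance data)."""
        scores = mutual_f(midnoise_corpus.annotations, "stance")
        assert max(scores, key=scores.get) == "Positive"


class TestReportAndMerge:
    def test_report_covers_all_categorizations(self, midnoise_corpus):
        report = agreement_report(midnoise_corpus.annotations)
        frame = report.to_frame()
        assert list(frame.index) == ["relevance", "subject", "stance", "sentiment"]
        assert ((frame >= -1) & (frame <= 1)).all().all()
        # relevance is easier to agree on than stance in the annotator model
        assert report.alpha["relevance"] > report.alpha["stance"]

    def test_merging_confused_categories_raises_alpha(self, midnoise_corpus):
        """Collapsing two confusable stance categories (e.g. Neutral and Not
        clear) cannot be told apart less often, so alpha increases."""
        records = midnoise_corpus.annotations
        merged = merge_labels(records, "stance", {"Not clear": "Neutral"})
        assert krippendorff_alpha(merged, "stance") > krippendorff_alpha(records, "stance")
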