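"""Metrics, baselines, ensembles, sweeps and cross-validated experiments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaxstance.evaluation import (
    ExperimentConfig,
    StratificationError,
    UndefinedAUCError,
    auc,
    binary_metrics,
    cross_validate,
    ensemble,
    f1_from_pr,
    learning_curve,
    precision_recall_f1,
    random_baseline,
    round_half_up,
    run_grid,
    threshold_sweep,
)
from vaxstance.harmonization import get_scheme, harmonize


def confusion_frame(tp, fp, fn, tn):
    return pd.DataFrame(
        [[tp, fn], [fp, tn]],
        index=["Negative", "Other"],
        columns=["Negative", "Other"],
    )


class TestBinaryMetrics:
    def test_perfect_predictions(self):
        assert binary_metrics(confusion_frame(10, 0, 0, 30)) == (1.0, 1.0, 1.0)

    def test_degenerate_counts_warn_and_return_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p, r, f1 = precision_recall_f1(0, 0, 5)
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_f1_is_harmonic_mean_of_reported_pr(self):
        p, r, f1 = binary_metrics(confusion_frame(161, 403, 182, 2104))
        assert f1 == pytest.approx(f1_from_pr(p, r), abs=1e-9)

    def test_missing_target_class_rejected(self):
        frame = pd.DataFrame([[1]], index=["Other"], columns=["Other"])
        with pytest.raises(ValueError, match="target"):
            binary_metrics(frame)

    def test_round_half_up_at_boundary(self):
        assert round_half_up(0.355, 2) == 0.36
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(0.1249, 2) == 0.12


class TestAUC:
    def test_perfect_ranking(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 1.0

    def test_single_class_truth_rejected(self):
        with pytest.raises(UndefinedAUCError):
            auc([0.1, 0.2], [True, True])

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = rng.random(n)
            truth = rng.random(n) < 0.4
            if truth.all() or not truth.any():
                continue
            pos = scores[truth]
            neg = scores[~truth]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            oracle = wins / (len(pos) * len(neg))
            assert auc(scores, truth) == pytest.approx(oracle, abs=1e-12)


class TestRandomBaseline:
    def test_rate_one_recalls_everything_at_prevalence_precision(self):
        truth = [True] * 30 + [False] * 70
        result = random_baseline(truth, rate=1.0, repeats=5, seed=1)
        assert result["recall"] == 1.0
        assert result["precision"] == pytest.approx(0.3)

    def test_rate_zero_scores_zero_f1(self):
        truth = [True] * 10 + [False] * 10
        result = random_baseline(truth, rate=0.0, repeats=5, seed=1)
        assert result["f1"] == 0.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            random_baseline([True, False], rate=0.5, repeats=0)
        with pytest.raises(ValueError):
            random_baseline([True, False], rate=1.5)


class TestEnsemble:
    def test_published_combination_rules(self):
        a = ["Negative", "Negative", "Other"]
        b = ["Negative", "Other", "Other"]
        assert list(ensemble(a, b, "precision")) == ["Negative", "Other", "Other"]
        assert list(ensemble(a, b, "recall")) == ["Negative", "Negative", "Other"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ensemble(["Negative"], ["Negative", "Other"], "recall")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            ensemble(["Negative"], ["Other"], "f1")

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["Negative", "Other"]),
                st.sampled_from(["Negative", "Other"]),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_conjunction_within_disjunction_bounds(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        n_and = (ensemble(a, b, "precision") == "Negative").sum()
        n_or = (ensemble(a, b, "recall") == "Negative").sum()
        n_a = sum(x == "Negative" for x in a)
        n_b = sum(x == "Negative" for x in b)
        assert n_and <= min(n_a, n_b) and max(n_a, n_b) <= n_or


@pytest.fixture(scope="module")
def separable_report(separable_corpus):
    instances = harmonize(separable_corpus.annotations, get_scheme("Binary"))
    config = ExperimentConfig(
        scheme="Binary", variant="strict", algorithm="svm",
        n_folds=10, seed=1, max_features=2_000,
    )
    return cross_validate(separable_corpus.texts(), instances, config)


@pytest.fixture(scope="module")
def sweep(separable_corpus):
    from vaxstance.classifiers import StanceClassifier
    from vaxstance.features import NgramVectorizer

    instances = harmonize(separable_corpus.annotations, get_scheme("Binary"))
    texts = separable_corpus.texts()
    docs = [texts[i.tweet_id] for i in instances]
    labels = np.array([i.label for i in instances], dtype=object)
    vec = NgramVectorizer(max_features=2_000)
    X = vec.fit(docs).transform(docs)
    preds = StanceClassifier(algorithm="svm").fit(X, labels).predict_set(X)
    return threshold_sweep(preds, labels), preds, labels


class TestCrossValidation:
    def test_separable_corpus_is_solved(self, separable_report):
        assert separable_report.f1 >= 0.95
        assert separable_report.auc >= 0.99

    def test_reported_f1_consistent_with_pr(self, separable_report):
        expected = f1_from_pr(separable_report.precision, separable_report.recall)
        assert separable_report.f1 == pytest.approx(expected, abs=1e-9)

    def test_confusion_total_equals_evaluated_instances(self, separable_report):
        assert separable_report.confusion.to_numpy().sum() == separable_report.n_evaluated

    def test_one_metric_entry_per_fold(self, separable_report):
        assert len(separable_report.fold_metrics) == 10

    def test_scarce_class_raises_stratification_error(self, separable_corpus):
        instances = harmonize(separable_corpus.annotations, get_scheme("Binary"))
        config = ExperimentConfig(scheme="Binary", variant="strict", n_folds=10_000)
        with pytest.raises(StratificationError):
            cross_validate(separable_corpus.texts(), instances, config)

    def test_mini_grid_produces_one_report_per_cell(self, midnoise_corpus):
        instances = {"Binary": harmonize(midnoise_corpus.annotations, get_scheme("Binary"))}
        reports = run_grid(
            midnoise_corpus.texts(),
            instances,
            schemes=("Binary",),
            variants=("strict", "strict+lax"),
            n_folds=5,
            max_features=2_000,
        )
        assert set(reports) == {
            "nb/Binary/strict", "svm/Binary/strict",
            "nb/Binary/strict+lax", "svm/Binary/strict+lax",
        }


class TestThresholdSweep:
    def test_recall_non_increasing_in_threshold(self, sweep):
        frame, _, _ = sweep
        recalls = frame.sort_values("threshold")["recall"].tolist()
        assert recalls == sorted(recalls, reverse=True)

    def test_perfectly_calibrated_scores_reach_perfect_point(self, sweep):
        frame, _, _ = sweep
        assert ((frame["precision"] == 1.0) & (frame["recall"] == 1.0)).any()

    def test_best_sweep_f1_at_least_argmax_f1(self, sweep):
        frame, preds, labels = sweep
        conf_default = pd.crosstab(labels, preds.labels)
        tp = conf_default.loc["Negative", "Negative"]
        fp = conf_default["Negative"].sum() - tp
        fn = conf_default.loc["Negative"].sum() - tp
        _, _, default_f1 = precision_recall_f1(int(tp), int(fp), int(fn))
        assert frame["f1"].max() >= default_f1 - 1e-12


class TestLearningCurve:
    def test_curve_grows_and_final_point_uses_full_pool(self, separable_corpus):
        instances = harmonize(separable_corpus.annotations, get_scheme("Binary"))
        config = ExperimentConfig(
            scheme="Binary", variant="strict", algorithm="svm",
            seed=1, max_features=2_000,
        )
        curve = learning_curve(
            separable_corpus.texts(), instances, config, n_points=4, pool="strict"
        )
        assert list(curve["fraction"]) == [0.25, 0.5, 0.75, 1.0]
        assert curve["n_train"].is_monotonic_increasing
        # with strong signal the curve ends at least as high as it starts
        assert curve["f1"].iloc[-1] >= curve["f1"].iloc[0]
        # the 100% point trains on the full pool: strict minus the 10% test split
        n_strict = sum(1 for i in instances if i.tier == "strict")
        assert abs(curve["n_train"].iloc[-1] - round(0.9 * n_strict)) <= 2
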