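"""Evaluation battery: cross-validated grids, baselines, ensembles, sweeps.

Systems are scored on how well they identify messages with a negative
stance: precision, recall and F1 on the Negative class plus the area under
the ROC curve of the Negative-class ranking scores.  Evaluation always runs
on the strictly labeled (reliably double-coded) data via stratified k-fold
cross-validation; lax and singly-annotated instances may augment each fold's
training set but never appear in a test fold.  Confusion counts are pooled
over folds and the AUC is computed on pooled out-of-fold scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classifiers import PredictionSet, StanceClassifier, predict_with_threshold
from .features import NgramVectorizer
from .harmonization import (
    VARIANT_TIERS,
    LabeledInstance,
    build_variant,
    get_scheme,
)


class StratificationError(ValueError):
    """A class has too few strict instances for the requested fold count."""


class UndefinedAUCError(ValueError):
    """AUC needs both a positive and a negative instance in the truth."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as in the printed report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# -- metrics ---------------------------------------------------------------

def precision_recall_f1(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    """Binary precision/recall/F1 from confusion counts; degenerate
    denominators yield 0 with a warning."""
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fp == 0 or tp + fn == 0:
        warnings.warn("degenerate confusion counts; reporting 0 metrics", stacklevel=2)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def binary_metrics(
    confusion: pd.DataFrame, target_class: str = "Negative"
) -> Tuple[float, float, float]:
    """Precision/recall/F1 of one target class from a (true x predicted)
    confusion table, collapsing all other classes."""
    if target_class not in confusion.index or target_class not in confusion.columns:
        raise ValueError(f"confusion table lacks target class {target_class!r}")
    tp = int(confusion.loc[target_class, target_class])
    fp = int(confusion[target_class].sum()) - tp
    fn = int(confusion.loc[target_class].sum()) - tp
    return precision_recall_f1(tp, fp, fn)


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of a printed precision/recall operating point."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Probability that a random positive outranks a random negative
    (Mann-Whitney formulation; ties count 1/2)."""
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise UndefinedAUCError("AUC undefined: truth contains a single class")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


# -- cross-validated experiments ------------------------------------------

@dataclass
class ExperimentConfig:
    """One cell of the experimental grid."""

    scheme: str = "Polarity"
    variant: str = "strict+lax"
    algorithm: str = "svm"
    n_folds: int = 10
    seed: int = 1
    target_class: str = "Negative"
    max_features: int = 15_000

    @property
    def system_id(self) -> str:
        return f"{self.algorithm}/{self.scheme}/{self.variant}"


@dataclass
class EvalReport:
    """Pooled Negative-class metrics and confusion table of one system."""

    system: str
    precision: float
    recall: float
    f1: float
    auc: float
    confusion: pd.DataFrame
    fold_metrics: List[Dict[str, float]] = field(default_factory=list)
    n_evaluated: int = 0
    #: pooled out-of-fold target-class probabilities and binary truth, for
    #: threshold sweeps and ranking diagnostics on cross-validated output
    scores: Optional[np.ndarray] = None
    truth_negative: Optional[np.ndarray] = None

    def precision_at_rate(self, rate: float) -> float:
        """Precision when flagging the top ``rate`` fraction by score."""
        if self.scores is None or not 0 < rate <= 1:
            raise ValueError("scores unavailable or rate outside (0, 1]")
        k = max(1, int(round(rate * self.scores.size)))
        top = np.argsort(-self.scores)[:k]
        return float(self.truth_negative[top].mean())

    def rounded(self, ndigits: int = 2) -> Dict[str, float]:
        return {
            "precision": round_half_up(self.precision, ndigits),
            "recall": round_half_up(self.recall, ndigits),
            "f1": round_half_up(self.f1, ndigits),
            "auc": round_half_up(self.auc, ndigits),
        }


def _confusion_frame(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str]
) -> pd.DataFrame:
    frame = pd.DataFrame(0, index=list(labels), columns=list(labels), dtype=int)
    for t, p in zip(y_true, y_pred):
        frame.loc[t, p] += 1
    frame.index.name = "truth"
    frame.columns.name = "predicted"
    return frame


def cross_validate(
    texts: Mapping[str, str],
    instances: Sequence[LabeledInstance],
    config: ExperimentConfig,
) -> EvalReport:
    """Stratified k-fold evaluation of one grid cell on the strict tier.

    Each fold trains on the strict training split plus the augmentation
    tiers of the configured variant, and is tested on the held-out strict
    split only.  Test/train disjointness is asserted on every fold.
    """
    scheme = get_scheme(config.scheme)
    strict = [inst for inst in instances if inst.tier == "strict"]
    augmentation = [
        inst
        for inst in instances
        if inst.tier != "strict" and inst.tier in VARIANT_TIERS[config.variant]
    ]
    labels = np.array([inst.label for inst in strict], dtype=object)
    label_values, label_counts_ = np.unique(labels, return_counts=True)
    if label_values.size < 2:
        raise StratificationError("strict data contain a single class")
    if label_counts_.min() < config.n_folds:
        scarce = label_values[label_counts_.argmin()]
        raise StratificationError(
            f"class {scarce!r} has {label_counts_.min()} strict instances, "
            f"fewer than n_folds={config.n_folds}"
        )

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    pooled_true: List[str] = []
    pooled_pred: List[str] = []
    pooled_scores: List[float] = []
    fold_metrics: List[Dict[str, float]] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(strict)), labels)):
        train_insts = [strict[i] for i in train_idx] + augmentation
        test_insts = [strict[i] for i in test_idx]
        train_ids = {inst.tweet_id for inst in train_insts}
        test_ids = {inst.tweet_id for inst in test_insts}
        assert not (train_ids & test_ids), "test fold leaked into training data"

        train_texts = [texts[inst.tweet_id] for inst in train_insts]
        train_labels = [inst.label for inst in train_insts]
        test_texts = [texts[inst.tweet_id] for inst in test_insts]
        test_labels = [inst.label for inst in test_insts]

        vectorizer = NgramVectorizer(max_features=config.max_features)
        X_train = vectorizer.fit(train_texts).transform(train_texts)
        X_test = vectorizer.transform(test_texts)
        clf = StanceClassifier(algorithm=config.algorithm, random_state=config.seed)
        clf.fit(X_train, np.array(train_labels, dtype=object))
        preds = clf.predict_set(X_test)

        pooled_true.extend(test_labels)
        pooled_pred.extend(preds.labels.tolist())
        pooled_scores.extend(preds.class_proba(config.target_class).tolist())
        fold_conf = _confusion_frame(test_labels, preds.labels, scheme.display_order)
        with warnings.catch_warnings():
            # a fold may legitimately predict no target instances
            warnings.simplefilter("ignore")
            p, r, f1 = binary_metrics(fold_conf, config.target_class)
        fold_metrics.append({"fold": fold, "precision": p, "recall": r, "f1": f1})

    confusion = _confusion_frame(pooled_true, pooled_pred, scheme.display_order)
    precision, recall, f1 = binary_metrics(confusion, config.target_class)
    pooled_truth = [t == config.target_class for t in pooled_true]
    return EvalReport(
        system=config.system_id,
        precision=precision,
        recall=recall,
        f1=f1,
        auc=auc(pooled_scores, pooled_truth),
        confusion=confusion,
        fold_metrics=fold_metrics,
        n_evaluated=len(pooled_true),
        scores=np.asarray(pooled_scores, dtype=float),
        truth_negative=np.asarray(pooled_truth, dtype=bool),
    )


def run_grid(
    texts: Mapping[str, str],
    instances_by_scheme: Mapping[str, Sequence[LabeledInstance]],
    algorithms: Sequence[str] = ("nb", "svm"),
    schemes: Sequence[str] = ("Binary", "IrrelevanceFilter", "Polarity", "PolaritySentiment"),
    variants: Sequence[str] = tuple(VARIANT_TIERS),
    n_folds: int = 10,
    seed: int = 1,
    max_features: int = 15_000,
) -> Dict[str, EvalReport]:
    """The full experimental grid: every labeling scheme x training-data
    variant x algorithm (4 x 4 x 2 = 32 systems by default), keyed by
    system id."""
    reports: Dict[str, EvalReport] = {}
    for scheme in schemes:
        for variant in variants:
            for algorithm in algorithms:
                config = ExperimentConfig(
                    scheme=scheme,
                    variant=variant,
                    algorithm=algorithm,
                    n_folds=n_folds,
                    seed=seed,
                    max_features=max_features,
                )
                reports[config.system_id] = cross_validate(
                    texts, instances_by_scheme[scheme], config
                )
    return reports


def grid_summary(reports: Mapping[str, EvalReport]) -> pd.DataFrame:
    """F1/AUC per system, one row per (algorithm, scheme, variant)."""
    rows = []
    for system, report in reports.items():
        algorithm, scheme, variant = system.split("/")
        rows.append(
            {
                "algorithm": algorithm,
                "scheme": scheme,
                "variant": variant,
                "precision": report.precision,
                "recall": report.recall,
                "f1": report.f1,
                "auc": report.auc,
            }
        )
    return pd.DataFrame(rows)


# -- baselines, ensembles, sweeps -----------------------------------------

def random_baseline(
    truth_negative: Sequence[bool],
    rate: float,
    repeats: int = 1000,
    seed: int = 0,
) -> Dict[str, float]:
    """Random system labeling each message Negative with probability ``rate``
    and scoring it uniform(0,1); metrics averaged over seeded repeats."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0,1]")
    truth = np.asarray(truth_negative, dtype=bool)
    rng = np.random.default_rng(seed)
    sums = {"precision": 0.0, "recall": 0.0, "f1": 0.0, "auc": 0.0}
    for _ in range(repeats):
        pred = rng.random(truth.size) < rate
        tp = int(np.sum(pred & truth))
        fp = int(np.sum(pred & ~truth))
        fn = int(np.sum(~pred & truth))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r, f1 = precision_recall_f1(tp, fp, fn)
        sums["precision"] += p
        sums["recall"] += r
        sums["f1"] += f1
        sums["auc"] += auc(rng.random(truth.size), truth)
    return {k: v / repeats for k, v in sums.items()}


def ensemble(
    pred_a: Sequence[str],
    pred_b: Sequence[str],
    mode: str,
    negative_label: str = "Negative",
    other_label: str = "Other",
) -> np.ndarray:
    """Combine two systems' binary stance decisions.

    ``precision`` mode flags Negative only when both systems do
    (conjunction); ``recall`` mode when at least one does (disjunction).
    """
    a = np.asarray(pred_a, dtype=object)
    b = np.asarray(pred_b, dtype=object)
    if a.shape != b.shape:
        raise ValueError(f"prediction length mismatch: {a.shape} vs {b.shape}")
    neg_a = a == negative_label
    neg_b = b == negative_label
    if mode == "precision":
        combined = neg_a & neg_b
    elif mode == "recall":
        combined = neg_a | neg_b
    else:
        raise ValueError(f"mode must be 'precision' or 'recall', got {mode!r}")
    return np.where(combined, negative_label, other_label)


def threshold_sweep(
    predictions: PredictionSet,
    truth: Sequence[str],
    target_class: str = "Negative",
    grid: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Precision/recall/F1 at every decision threshold on the target class's
    probability; recall is non-increasing as the threshold rises."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    truth = np.asarray(truth, dtype=object)
    is_target = truth == target_class
    rows = []
    for threshold in grid:
        pred = predict_with_threshold(predictions, target_class, float(threshold))
        tp = int(np.sum((pred == target_class) & is_target))
        fp = int(np.sum((pred == target_class) & ~is_target))
        fn = int(np.sum((pred != target_class) & is_target))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r, f1 = precision_recall_f1(tp, fp, fn)
        rows.append({"threshold": float(threshold), "precision": p, "recall": r, "f1": f1})
    return pd.DataFrame(rows)


def learning_curve(
    texts: Mapping[str, str],
    instances: Sequence[LabeledInstance],
    config: ExperimentConfig,
    n_points: int = 10,
    pool: str = "strict+lax",
    test_fraction: float = 0.1,
) -> pd.DataFrame:
    """Performance on a fixed strict test split as training data grows.

    A stratified ``test_fraction`` of the strict tier is held out once; the
    training pool is the remaining strict data plus the augmentation tiers
    of ``pool``.  Nested subsets (10%, 20%, ... 100% under one seeded
    shuffle) are trained and scored; points whose subset lacks two classes
    are skipped with a warning.
    """
    strict = [inst for inst in instances if inst.tier == "strict"]
    labels = np.array([inst.label for inst in strict], dtype=object)
    n_test_folds = max(2, int(round(1.0 / test_fraction)))
    skf = StratifiedKFold(n_splits=n_test_folds, shuffle=True, random_state=config.seed)
    train_idx, test_idx = next(skf.split(np.zeros(len(strict)), labels))
    test_insts = [strict[i] for i in test_idx]
    pool_insts = [strict[i] for i in train_idx] + [
        inst
        for inst in instances
        if inst.tier != "strict" and inst.tier in VARIANT_TIERS[pool]
    ]
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(pool_insts))

    test_texts = [texts[inst.tweet_id] for inst in test_insts]
    test_labels = [inst.label for inst in test_insts]
    is_target = np.array([l == config.target_class for l in test_labels])
    scheme = get_scheme(config.scheme)

    rows = []
    for point in range(1, n_points + 1):
        fraction = point / n_points
        n_train = max(1, int(round(fraction * len(pool_insts))))
        subset = [pool_insts[i] for i in order[:n_train]]
        train_labels = [inst.label for inst in subset]
        if len(set(train_labels)) < 2:
            warnings.warn(
                f"learning-curve point at fraction {fraction:.2f} skipped: "
                "subset contains a single class"
            )
            continue
        train_texts = [texts[inst.tweet_id] for inst in subset]
        vectorizer = NgramVectorizer(max_features=config.max_features)
        X_train = vectorizer.fit(train_texts).transform(train_texts)
        X_test = vectorizer.transform(test_texts)
        clf = StanceClassifier(algorithm=config.algorithm, random_state=config.seed)
        clf.fit(X_train, np.array(train_labels, dtype=object))
        preds = clf.predict_set(X_test)
        conf = _confusion_frame(test_labels, preds.labels, scheme.display_order)
        _, _, f1 = binary_metrics(conf, config.target_class)
        point_auc = auc(preds.class_proba(config.target_class), is_target)
        rows.append(
            {"fraction": fraction, "n_train": n_train, "f1": f1, "auc": point_auc}
        )
    return pd.DataFrame(rows)
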