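"""Statistical stance classifiers over binary n-gram features.

Two algorithms are supported with the settings used in the study:

* multinomial naive Bayes with (near-)zero additive smoothing and a muted
  class prior, and
* a linear support-vector machine with C = 1.0 and balanced class weights
  (each class's loss contribution scaled by total / (n_classes * count)).

Both expose per-class ranking scores and calibrated probabilities so that
the Negative-class decision threshold can be moved along the
precision-recall trade-off.  The SVM has no native probabilities; decision
values are mapped through a Platt-style logistic calibration fitted on the
training data (3-fold internally), one-vs-rest for multiclass problems.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.exceptions import NotFittedError
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import LinearSVC
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted

#: Stand-in for literal zero additive smoothing: a zero-count feature
#: likelihood becomes this epsilon instead of log(0).
NB_ALPHA_EPSILON = 1e-10

ALGORITHMS = ("nb", "svm")


@dataclass
class PredictionSet:
    """Per-tweet ranking scores, calibrated probabilities and decided labels.

    ``scores`` and ``proba`` are (n_samples, n_classes) arrays over
    ``classes``; ``labels`` is the argmax-of-probability decision unless a
    threshold override produced it.
    """

    classes: np.ndarray
    scores: np.ndarray
    proba: np.ndarray
    labels: np.ndarray

    def class_index(self, label: str) -> int:
        idx = np.flatnonzero(self.classes == label)
        if idx.size == 0:
            raise ValueError(f"class {label!r} unknown to this prediction set")
        return int(idx[0])

    def class_proba(self, label: str) -> np.ndarray:
        return self.proba[:, self.class_index(label)]


class StanceClassifier(BaseEstimator, ClassifierMixin):
    """Naive Bayes or linear-SVM stance classifier with calibrated scores.

    Parameters
    ----------
    algorithm : {"svm", "nb"}
        Which statistical model to fit.
    nb_alpha : float, default 0.0
        Additive smoothing for naive Bayes.  Literal zero is realized as an
        epsilon of 1e-10 so zero-count likelihoods never take log(0).
    nb_fit_prior : bool, default False
        Whether naive Bayes learns class priors; muted (uniform) by default.
    svm_C : float, default 1.0
        SVM regularization parameter.
    svm_class_weight : "balanced" or None, default "balanced"
    calibration_folds : int, default 3
        Internal folds for the Platt-style sigmoid calibration of SVM
        decision values.
    random_state : int, default 0
    """

    def __init__(
        self,
        algorithm: str = "svm",
        nb_alpha: float = 0.0,
        nb_fit_prior: bool = False,
        svm_C: float = 1.0,
        svm_class_weight: Optional[str] = "balanced",
        calibration_folds: int = 3,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.nb_alpha = nb_alpha
        self.nb_fit_prior = nb_fit_prior
        self.svm_C = svm_C
        self.svm_class_weight = svm_class_weight
        self.calibration_folds = calibration_folds
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y) -> "StanceClassifier":
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} rows but y has {y.shape[0]} labels"
            )
        self.classes_ = unique_labels(y)
        if self.classes_.size < 2:
            raise ValueError("training data must contain at least 2 distinct labels")
        if self.algorithm == "nb":
            alpha = self.nb_alpha if self.nb_alpha > 0 else NB_ALPHA_EPSILON
            self.model_ = MultinomialNB(alpha=alpha, fit_prior=self.nb_fit_prior)
            self.model_.fit(X, y)
            self.calibrator_ = None
        else:
            self.model_ = LinearSVC(
                C=self.svm_C,
                class_weight=self.svm_class_weight,
                random_state=self.random_state,
            )
            self.model_.fit(X, y)
            n_folds = min(self.calibration_folds, int(np.bincount(
                np.searchsorted(self.classes_, y)).min()))
            self.calibrator_ = CalibratedClassifierCV(
                LinearSVC(
                    C=self.svm_C,
                    class_weight=self.svm_class_weight,
                    random_state=self.random_state,
                ),
                method="sigmoid",
                cv=max(2, n_folds),
            )
            self.calibrator_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    # -- prediction --------------------------------------------------------

    def _check_fitted(self):
        try:
            check_is_fitted(self, "model_")
        except NotFittedError:
            raise NotFittedError(
                "this StanceClassifier is not fitted yet; call fit first"
            ) from None

    def decision_scores(self, X) -> np.ndarray:
        """Per-class ranking scores: joint log-likelihood for NB, one-vs-rest
        decision values for the SVM (shape (n_samples, n_classes))."""
        self._check_fitted()
        if self.algorithm == "nb":
            return self.model_.predict_joint_log_proba(X)
        scores = self.model_.decision_function(X)
        if scores.ndim == 1:  # binary: single margin, expand to two columns
            scores = np.column_stack([-scores, scores])
        return scores

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        if self.algorithm == "nb":
            return self.model_.predict_proba(X)
        return self.calibrator_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def predict_set(self, X) -> PredictionSet:
        """Scores, probabilities and argmax labels in one container."""
        proba = self.predict_proba(X)
        return PredictionSet(
            classes=self.classes_.copy(),
            scores=self.decision_scores(X),
            proba=proba,
            labels=self.classes_[np.argmax(proba, axis=1)],
        )


def reference_spec(algorithm: str, random_state: int = 0) -> StanceClassifier:
    """A classifier constructed with the reference study's settings (NB with
    zero smoothing and muted prior; linear SVM with C=1.0, balanced)."""
    return StanceClassifier(algorithm=algorithm, random_state=random_state)


def predict_with_threshold(
    predictions: PredictionSet,
    target_class: str = "Negative",
    threshold: float = 0.5,
    other_label: str = "Other",
) -> np.ndarray:
    """Binary decision by thresholding the target class's probability.

    The target class is predicted iff its calibrated probability is >= the
    threshold; threshold 0 labels everything as target, any threshold above
    1 labels nothing.
    """
    p = predictions.class_proba(target_class)
    return np.where(p >= threshold, target_class, other_label)
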