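"""Test-set evaluation: error rate, confusion matrix, ROC/AUC.

The confusion matrix is laid out predicted-class-by-observed-class (rows are
predictions).  For binary problems an ROC curve is computed by sweeping a
threshold over the predicted probability of the larger class label, and the
reported operating point maximizes sensitivity + specificity (Youden's J).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["EvaluationReport", "evaluate"]


@dataclass(frozen=True)
class EvaluationReport:
    """Classifier performance summary on a labeled test set.

    Attributes
    ----------
    error_rate : float
        Misclassification fraction in [0, 1].
    confusion : numpy.ndarray of shape (L, L)
        Counts, rows = predicted class, columns = observed class; entries
        sum to the test size.
    classes : numpy.ndarray
        Class labels indexing the confusion matrix.
    roc_points : numpy.ndarray of shape (n_thresholds, 3) or None
        Columns (false-positive rate, true-positive rate, threshold);
        binary problems only.
    auc : float or None
        Area under the ROC curve (trapezoidal rule).
    best_threshold : float or None
        Probability threshold maximizing sensitivity + specificity.
    """

    error_rate: float
    confusion: np.ndarray
    classes: np.ndarray
    roc_points: np.ndarray | None = None
    auc: float | None = None
    best_threshold: float | None = None


def evaluate(model, X_test, y_test) -> EvaluationReport:
    """Evaluate a fitted classifier on a labeled test set.

    ``model`` must expose ``classes_``, ``predict`` and ``predict_proba``.
    For binary problems the ROC treats ``classes_[1]`` as the positive class.
    """
    y_test = np.asarray(y_test)
    proba = model.predict_proba(X_test)
    pred = model.classes_[proba.argmax(axis=1)]
    error_rate = float(np.mean(pred != y_test))
    # sklearn returns observed-by-predicted; transpose to predicted-by-observed
    confusion = _sk_confusion(y_test, pred, labels=model.classes_).T
    roc_points = auc = best_threshold = None
    if len(model.classes_) == 2:
        if len(np.unique(y_test)) < 2:
            warnings.warn(
                "test set contains a single class; ROC omitted", stacklevel=2
            )
        else:
            scores = proba[:, 1]
            fpr, tpr, thr = _sk_roc_curve(
                y_test, scores, pos_label=model.classes_[1]
            )
            roc_points = np.column_stack([fpr, tpr, thr])
            auc = float(_trapezoid_auc(fpr, tpr))
            best = np.argmax(tpr - fpr)  # sensitivity + specificity - 1
            best_threshold = float(thr[best])
    return EvaluationReport(
        error_rate=error_rate,
        confusion=confusion,
        classes=model.classes_,
        roc_points=roc_points,
        auc=auc,
        best_threshold=best_threshold,
    )
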