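"""The aggregated probabilistic nearest neighbors classifier.

For each neighbor rank ``r`` a nonlocal label model is fitted by maximum
likelihood on the training sample (see :mod:`pnnclass.partition`).  A query
point's predictive distribution under the rank-``r`` model is

    p_r(label = l)  ∝  exp( beta_hat_r * [ I(l = y_{[q]_r})
                                           + #captured units with label l ] )

where ``[q]_r`` is the query's r-th nearest training unit and the *captured*
units are those whose own r-th nearest neighbor becomes the query once it is
inserted into the sample.  The first ``k`` per-rank distributions are
aggregated by arithmetic mean,

    p^(k) = (1/k) * sum_{r=1..k} p_r,

and ``k`` is chosen by leave-one-out cross-validation on the training sample.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba``, ``classes_``, ``get_params``); it is deterministic —
identical inputs produce bit-identical models and predictions.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .cycles import CycleCounts, count_simple_cycles
from .neighbors import (
    InsertionNeighborhood,
    capture_ranks,
    compute_brackets,
    compute_distance_matrix,
)
from .partition import DEFAULT_BETA_MAX, NonlocalFit, fit_beta, sufficient_statistic

__all__ = ["PNNClassifier", "predict_r", "aggregate"]


def predict_r(fit: NonlocalFit, neigh: InsertionNeighborhood, labels, L: int) -> np.ndarray:
    """Predictive distribution of one rank-r nonlocal model for one query.

    ``probs[l] ∝ exp(beta_hat * s_l)`` with
    ``s_l = I(l = y_neighbor) + #{captured units with label l}``.
    """
    labels = np.asarray(labels, dtype=np.intp)
    s = np.zeros(L)
    s[labels[neigh.query_rth_neighbor]] += 1.0
    if len(neigh.captured_units):
        np.add.at(s, labels[neigh.captured_units], 1.0)
    logits = fit.beta_hat * s
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def aggregate(dists, k: int) -> np.ndarray:
    """Mean of the first ``k`` per-rank predictive distributions."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    dists = np.asarray(dists, dtype=float)
    if k > dists.shape[0]:
        raise ValueError(f"k={k} exceeds the {dists.shape[0]} available distributions")
    return dists[:k].mean(axis=0)


class PNNClassifier(ClassifierMixin, BaseEstimator):
    """Probabilistic nearest neighbors classifier with exact per-rank likelihoods.

    Parameters
    ----------
    k_max : int or None, default=None
        Largest neighborhood size considered; ``None`` means ``n - 1``
        (values beyond ``n - 1`` are clipped with a warning).
    beta_max : float, default=30.0
        Upper bound for the per-rank interaction MLE; fits hitting it are
        flagged as clipped.
    loocv_refit : bool, default=False
        If True, re-estimate every rank's interaction strength within each
        leave-one-out fold (exact but O(n) times slower).  By default the
        per-rank MLEs are fitted once on the full training sample and reused
        across folds.
    metric : {"euclidean", "precomputed"}, default="euclidean"
        With "precomputed", ``fit`` expects a square distance matrix and
        ``predict``/``predict_proba`` expect query-to-training distances.

    Attributes
    ----------
    classes_ : ndarray of shape (L,)
        Class labels in sorted order.
    distance_matrix_ : ndarray of shape (n, n)
        Training distances.
    brackets_ : ndarray of shape (n, n-1)
        Distance-ranked neighbor indices.
    cycle_counts_ : CycleCounts
        Simple-cycle census of every rank-r neighbor digraph.
    fits_ : list of NonlocalFit
        Per-rank maximum-likelihood fits, ranks 1..k_max.
    k_ : int
        Neighborhood size selected by leave-one-out cross-validation.
    loocv_error_ : ndarray of shape (k_max,)
        Leave-one-out misclassification rate for each candidate ``k``.

    Examples
    --------
    >>> from pnnclass import PNNClassifier
    >>> from pnnclass.datasets import ripley_like
    >>> train, test = ripley_like(seed=7)
    >>> clf = PNNClassifier().fit(train.X, train.y)
    >>> err = 1.0 - clf.score(test.X, test.y)
    """

    def __init__(self, k_max=None, beta_max=DEFAULT_BETA_MAX, loocv_refit=False,
                 metric="euclidean"):
        self.k_max = k_max
        self.beta_max = beta_max
        self.loocv_refit = loocv_refit
        self.metric = metric

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        """Fit per-rank models and select the neighborhood size by LOOCV."""
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=3)
        if self.metric not in ("euclidean", "precomputed"):
            raise ValueError(f"unknown metric {self.metric!r}")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        n = X.shape[0]
        self.n_features_in_ = X.shape[1]
        if self.metric == "precomputed":
            if X.shape[0] != X.shape[1]:
                raise ValueError("precomputed metric requires a square matrix")
            self.distance_matrix_ = np.asarray(X, dtype=float)
            self._X_train = None
        else:
            self.distance_matrix_ = compute_distance_matrix(X)
            self._X_train = X
        self._y_enc = y_enc
        self.brackets_ = compute_brackets(self.distance_matrix_)
        self.cycle_counts_ = count_simple_cycles(self.brackets_)

        k_max = n - 1 if self.k_max is None else int(self.k_max)
        if k_max > n - 1:
            warnings.warn(
                f"k_max={k_max} exceeds n-1={n - 1}; clipping", stacklevel=2
            )
            k_max = n - 1
        if k_max < 1:
            raise ValueError(f"k_max must be >= 1, got {k_max}")
        self.k_max_ = k_max

        L = len(self.classes_)
        self.fits_ = [
            fit_beta(
                sufficient_statistic(y_enc, self.brackets_, r),
                L, n, self.cycle_counts_.for_rank(r),
                r=r, beta_max=self.beta_max,
            )
            for r in range(1, k_max + 1)
        ]
        self.betas_ = np.array([f.beta_hat for f in self.fits_])
        self.k_, self.loocv_error_ = self.loocv_select_k()
        return self

    # --------------------------------------------------------------- loocv

    def loocv_select_k(self):
        """Leave-one-out selection of the aggregation size ``k``.

        Each training unit is predicted from the remaining ``n - 1``: its
        rank-``r`` neighbor is read from the full brackets and the captured
        set is ``{j : [j]_r = i}``.  Returns ``(k_selected, error_curve)``;
        error ties resolve to the smallest ``k``.
        """
        if self.loocv_refit:
            probs = self._loocv_probs_refit()
        else:
            probs = self._loocv_probs_shared()
        # running mean over ranks, then argmax per k (ties -> smaller label)
        k_eff = probs.shape[1]
        cum = probs.cumsum(axis=1) / np.arange(1, k_eff + 1)[None, :, None]
        preds = cum.argmax(axis=2)
        errors = (preds != self._y_enc[:, None]).mean(axis=0)
        if k_eff < self.k_max_:  # refit mode caps k at n-2
            errors = np.concatenate([errors, np.repeat(errors[-1], self.k_max_ - k_eff)])
        return int(errors.argmin()) + 1, errors

    def _loocv_probs_shared(self) -> np.ndarray:
        """Per-fold per-rank predictive distributions, reusing full-sample fits."""
        n = self.brackets_.shape[0]
        L = len(self.classes_)
        k_max, y_enc = self.k_max_, self._y_enc
        # pos[j, i] = rank of unit i in unit j's neighbor list (diag unused)
        pos = np.zeros((n, n), dtype=np.intp)
        pos[np.arange(n)[:, None], self.brackets_] = np.arange(1, n)
        s = np.zeros((n, k_max, L))
        rows = np.arange(n)[:, None]
        cols = np.arange(k_max)[None, :]
        s[rows, cols, y_enc[self.brackets_[:, :k_max]]] += 1.0
        J, I = np.nonzero((pos >= 1) & (pos <= k_max))
        np.add.at(s, (I, pos[J, I] - 1, y_enc[J]), 1.0)
        logits = self.betas_[None, :k_max, None] * s
        logits -= logits.max(axis=2, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=2, keepdims=True)

    def _loocv_probs_refit(self) -> np.ndarray:
        """Exact LOOCV: per-fold bracket rebuild and per-rank re-estimation."""
        n = self.brackets_.shape[0]
        L = len(self.classes_)
        k_eff = min(self.k_max_, n - 2)
        probs = np.empty((n, k_eff, L))
        for i in range(n):
            keep = np.delete(np.arange(n), i)
            d_sub = self.distance_matrix_[np.ix_(keep, keep)]
            y_sub = self._y_enc[keep]
            brackets = compute_brackets(d_sub)
            counts = count_simple_cycles(brackets)
            q = self.distance_matrix_[i, keep]
            order = np.argsort(q, kind="stable")
            cap = capture_ranks(d_sub, q)
            for r in range(1, k_eff + 1):
                f = fit_beta(
                    sufficient_statistic(y_sub, brackets, r),
                    L, n - 1, counts.for_rank(r),
                    r=r, beta_max=self.beta_max,
                )
                sc = np.zeros(L)
                sc[y_sub[order[r - 1]]] += 1.0
                captured = np.flatnonzero(cap == r)
                if captured.size:
                    np.add.at(sc, y_sub[captured], 1.0)
                logits = f.beta_hat * sc
                logits -= logits.max()
                e = np.exp(logits)
                probs[i, r - 1] = e / e.sum()
        return probs

    # ------------------------------------------------------------- predict

    def _query_distance_rows(self, X) -> np.ndarray:
        X = check_array(X, dtype=float)
        if self.metric == "precomputed":
            if X.shape[1] != self.distance_matrix_.shape[0]:
                raise ValueError(
                    f"precomputed query matrix must have {self.distance_matrix_.shape[0]} "
                    f"columns (one per training unit), got {X.shape[1]}"
                )
            return X
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"queries have {X.shape[1]} features, model was fitted with "
                f"{self.n_features_in_}"
            )
        from scipy.spatial.distance import cdist

        return cdist(X, self._X_train)

    def predict_proba(self, X) -> np.ndarray:
        """Aggregated predictive distribution for each query row.

        Returns an ``(n_queries, L)`` array; columns follow ``classes_`` and
        each row sums to 1.
        """
        check_is_fitted(self, "fits_")
        q_rows = self._query_distance_rows(X)
        n = self.distance_matrix_.shape[0]
        L = len(self.classes_)
        k, y_enc = self.k_, self._y_enc
        betas = self.betas_[:k]
        out = np.empty((q_rows.shape[0], L))
        ranks_r = np.arange(k)
        for qi, q in enumerate(q_rows):
            order = np.argsort(q, kind="stable")
            cap = capture_ranks(self.distance_matrix_, q)
            s = np.zeros((k, L))
            s[ranks_r, y_enc[order[:k]]] += 1.0
            mask = cap <= k
            if mask.any():
                np.add.at(s, (cap[mask] - 1, y_enc[mask]), 1.0)
            logits = betas[:, None] * s
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            out[qi] = p.mean(axis=0)
        return out

    def predict(self, X) -> np.ndarray:
        """Most probable class per query; probability ties resolve to the
        smallest class label."""
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]
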