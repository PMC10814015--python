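"""Distance matrices, neighbor brackets and insertion-aware neighbor queries.

The classifier is built on a distance-ranked neighbor structure: for each
training unit ``i``, ``brackets[i, r-1]`` is the index of its ``r``-th nearest
neighbor (0-based unit indices, ranks ``r = 1, ..., n-1``).  Prediction for a
query point needs the *insertion* view of the same structure: where the query
lands in each unit's neighbor ranking once it is added to the sample, without
rebuilding the ranking from scratch.

Tie conventions (applied everywhere, so results are deterministic):

* equidistant training units are ranked by smaller unit index;
* when a query point is exactly as far from a unit as one of that unit's
  training neighbors, the training neighbor keeps the earlier rank (the query
  is ranked after it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "compute_distance_matrix",
    "compute_brackets",
    "insertion_neighborhood",
    "query_distances",
    "capture_ranks",
    "InsertionNeighborhood",
]


@dataclass(frozen=True)
class InsertionNeighborhood:
    """Neighbor relations between a query point and the training sample at rank ``r``.

    Attributes
    ----------
    query_rth_neighbor : int
        Index of the training unit that is the query's ``r``-th nearest
        neighbor.
    captured_units : numpy.ndarray of int
        Training units whose ``r``-th nearest neighbor becomes the query once
        the query is inserted into the sample.
    """

    query_rth_neighbor: int
    captured_units: np.ndarray


def _validate_features(features) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError(f"features must be a 2-d array, got ndim={x.ndim}")
    if x.shape[0] < 3:
        raise ValueError(f"need at least 3 sample units, got {x.shape[0]}")
    if not np.isfinite(x).all():
        bad = np.argwhere(~np.isfinite(x))[0]
        raise ValueError(
            f"features contain a non-finite value at row {bad[0]}, column {bad[1]}"
        )
    return x


def compute_distance_matrix(features) -> np.ndarray:
    """Pairwise Euclidean distance matrix of a feature matrix.

    Parameters
    ----------
    features : array-like of shape (n, p)
        Numeric predictor matrix; rows are sample units.

    Returns
    -------
    numpy.ndarray of shape (n, n)
        Symmetric matrix with zero diagonal.
    """
    x = _validate_features(features)
    d = squareform(pdist(x, metric="euclidean"))
    return d


def _validate_distance_matrix(d) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {d.shape}")
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains non-finite entries")
    if (d < 0).any():
        raise ValueError("distance matrix contains negative entries")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    if np.abs(np.diag(d)).max(initial=0.0) != 0.0:
        raise ValueError("distance matrix diagonal must be zero")
    return d


def compute_brackets(d) -> np.ndarray:
    """Rank the other units by distance for every unit.

    Parameters
    ----------
    d : array-like of shape (n, n)
        Valid distance matrix (symmetric, zero diagonal, nonnegative).

    Returns
    -------
    numpy.ndarray of shape (n, n-1)
        Row ``i`` lists the other ``n-1`` unit indices by increasing distance
        from ``i``; ties broken by smaller index.  Column ``r-1`` holds the
        ``r``-th nearest neighbor.
    """
    d = _validate_distance_matrix(d)
    n = d.shape[0]
    work = d.copy()
    np.fill_diagonal(work, np.inf)  # self is never its own neighbor
    # stable sort => equal distances keep index order (smaller index first)
    order = np.argsort(work, axis=1, kind="stable")
    return order[:, : n - 1]


def query_distances(train_features, query) -> np.ndarray:
    """Euclidean distances from one query point to every training unit."""
    x = np.asarray(train_features, dtype=float)
    q = np.asarray(query, dtype=float).reshape(1, -1)
    if q.shape[1] != x.shape[1]:
        raise ValueError(
            f"query has {q.shape[1]} features, training data has {x.shape[1]}"
        )
    return cdist(q, x)[0]


def capture_ranks(d_train, query_dists) -> np.ndarray:
    """Rank that the query would occupy in each unit's augmented neighbor list.

    For unit ``i`` the returned value is ``1 +`` the number of training units
    (self excluded) at distance ``<= query_dists[i]`` from ``i`` — i.e. the
    rank of the query among ``i``'s neighbors once inserted, with training
    units winning ties.
    """
    d_train = np.asarray(d_train, dtype=float)
    q = np.asarray(query_dists, dtype=float)
    # d(i,i)=0 <= q_i always counts once; subtract it back out
    closer = (d_train <= q[:, None]).sum(axis=1) - 1
    return closer + 1


def insertion_neighborhood(d_train, brackets, query_dists, r: int) -> InsertionNeighborhood:
    """Neighbor relations induced by inserting a query point, at rank ``r``.

    Equivalent to rebuilding the full bracket structure on the augmented
    ``(n+1)``-point sample and reading off the query's ``r``-th neighbor and
    the set ``{i : [i]_r = query}`` — but in O(n log n).

    Parameters
    ----------
    d_train : array-like of shape (n, n)
        Training distance matrix.
    brackets : array-like of shape (n, n-1)
        Output of :func:`compute_brackets` for ``d_train`` (accepted for
        interface symmetry; the capture test uses distance counts directly).
    query_dists : array-like of shape (n,)
        Distances from the query to each training unit.
    r : int
        Neighbor rank, ``1 <= r <= n-1``.
    """
    d_train = np.asarray(d_train, dtype=float)
    q = np.asarray(query_dists, dtype=float)
    n = d_train.shape[0]
    if not 1 <= r <= n - 1:
        raise ValueError(f"rank r={r} out of range [1, {n - 1}]")
    order = np.argsort(q, kind="stable")
    ranks = capture_ranks(d_train, q)
    captured = np.flatnonzero(ranks == r)
    return InsertionNeighborhood(
        query_rth_neighbor=int(order[r - 1]), captured_units=captured
    )
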