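"""Shared fixtures and independent reference implementations.

The reference routines here deliberately use different algorithms from the
package (double loops, full recomputation, successor iteration) so that a bug
cannot hide in both paths at once.
"""

import numpy as np
import pytest

from pnnclass.neighbors import compute_brackets


def brute_distance_matrix(X):
    """Double-loop Euclidean distances."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum())
    return d


def rebuild_insertion(d_train, query_dists, r):
    """Insertion relations by full bracket recomputation on the augmented set.

    Appends the query as unit ``n`` (largest index, so it loses distance ties
    to every training unit under the stable lower-index rule) and reads the
    answers off the rebuilt brackets.
    """
    d_train = np.asarray(d_train, dtype=float)
    q = np.asarray(query_dists, dtype=float)
    n = d_train.shape[0]
    d_aug = np.zeros((n + 1, n + 1))
    d_aug[:n, :n] = d_train
    d_aug[n, :n] = q
    d_aug[:n, n] = q
    brackets = compute_brackets(d_aug)
    query_rth = int(brackets[n, r - 1])
    captured = np.flatnonzero(brackets[:n, r - 1] == n)
    return query_rth, captured


@pytest.fixture
def line_points():
    """The 1-D three-point configuration {0, 1, 3} used in worked examples."""
    return np.array([[0.0], [1.0], [3.0]])


@pytest.fixture
def separated_clusters():
    """Two label-pure, well-separated 2-D clusters (deterministic)."""
    rng = np.random.default_rng(11)
    a = rng.normal(loc=(0.0, 0.0), scale=0.3, size=(15, 2))
    b = rng.normal(loc=(10.0, 10.0), scale=0.3, size=(15, 2))
    X = np.vstack([a, b])
    y = np.repeat([0, 1], 15)
    return X, y
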