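"""Seeded synthetic benchmark generators.

Two generators emulate the structure of the classic benchmark settings for
nearest-neighbor classifiers without shipping or downloading any data:

* :func:`ripley_like` — a two-class, two-dimensional problem where each class
  is an equal-weight mixture of two isotropic Gaussians with overlapping
  supports, in the mold of Ripley's synthetic training/test benchmark
  (250 training and 1000 test points by default).  The default component
  means and variance are this package's choices, set so that a well-tuned
  majority-vote k-NN lands in roughly the 8-12% test-error band.
* :func:`multiclass_blobs` — L Gaussian blobs with a separation dial, for
  multiclass behavior from perfectly separable to pure noise.

Both are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LabeledDataset",
    "ripley_like",
    "multiclass_blobs",
    "random_functional_graph",
    "RIPLEY_MEANS",
    "RIPLEY_VARIANCE",
]

# per-class component means (two components each) and shared isotropic variance
RIPLEY_MEANS = {
    0: np.array([[-0.7, 0.3], [0.3, 0.3]]),
    1: np.array([[-0.3, 0.7], [0.4, 0.7]]),
}
RIPLEY_VARIANCE = 0.03


@dataclass(frozen=True)
class LabeledDataset:
    """A feature matrix with integer-coded class labels.

    Attributes
    ----------
    X : numpy.ndarray of shape (n, p)
        Numeric predictors.
    y : numpy.ndarray of shape (n,)
        Integer labels in ``{0, ..., L-1}``.
    """

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=np.intp)
        if X.ndim != 2:
            raise ValueError("X must be 2-d")
        if y.shape != (X.shape[0],):
            raise ValueError("y must be a vector matching X's row count")
        if X.shape[0] >= 1 and (y < 0).any():
            raise ValueError("labels must be nonnegative integer codes")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def L(self) -> int:
        return int(self.y.max()) + 1 if self.n else 0


def _sample_mixture(rng, n, means_by_class, variance, class_probs):
    K = len(means_by_class)
    y = rng.choice(K, size=n, p=class_probs)
    X = np.empty((n, means_by_class[0].shape[1]))
    for c in range(K):
        idx = np.flatnonzero(y == c)
        means = means_by_class[c]
        comp = rng.integers(means.shape[0], size=idx.size)
        X[idx] = means[comp] + rng.normal(
            scale=np.sqrt(variance), size=(idx.size, means.shape[1])
        )
    return X, y


def ripley_like(
    n_train: int = 250,
    n_test: int = 1000,
    means=None,
    variance: float = RIPLEY_VARIANCE,
    class_probs=(0.5, 0.5),
    seed=0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Two overlapping two-component Gaussian-mixture classes in the plane.

    Parameters
    ----------
    n_train, n_test : int
        Sample sizes (defaults 250 / 1000).
    means : mapping, optional
        ``{class: (n_components, 2) array}`` of component means; defaults to
        :data:`RIPLEY_MEANS`.
    variance : float
        Isotropic component variance (default 0.03).
    class_probs : pair of float
        Class prior probabilities; must sum to 1.
    seed : int or numpy Generator
        Randomness source; identical seeds give identical datasets.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("sample sizes must be >= 1")
    if variance <= 0:
        raise ValueError("variance must be > 0")
    class_probs = np.asarray(class_probs, dtype=float)
    if class_probs.min() < 0 or abs(class_probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_probs must be a probability vector")
    if means is None:
        means = RIPLEY_MEANS
    means_list = [np.atleast_2d(np.asarray(means[c], dtype=float)) for c in range(len(means))]
    rng = np.random.default_rng(seed)
    X_tr, y_tr = _sample_mixture(rng, n_train, means_list, variance, class_probs)
    X_te, y_te = _sample_mixture(rng, n_test, means_list, variance, class_probs)
    return LabeledDataset(X_tr, y_tr), LabeledDataset(X_te, y_te)


def multiclass_blobs(
    n_classes: int = 4,
    p: int = 2,
    n_train: int = 120,
    n_test: int = 120,
    separation: float = 3.0,
    variance: float = 1.0,
    seed=0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Balanced Gaussian blobs with a tunable between-class separation.

    Class means sit on a circle of radius ``separation`` in the first two
    coordinates (zero elsewhere); ``separation = 0`` collapses all classes
    onto one distribution (labels carry no signal), large separation makes
    the problem trivially separable.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if p < 1 or n_train < 1 or n_test < 1:
        raise ValueError("dimensions and sample sizes must be >= 1")
    angles = 2 * np.pi * np.arange(n_classes) / n_classes
    means = np.zeros((n_classes, p))
    means[:, 0] = separation * np.cos(angles)
    if p > 1:
        means[:, 1] = separation * np.sin(angles)
    rng = np.random.default_rng(seed)

    def draw(n):
        y = rng.integers(n_classes, size=n)
        X = means[y] + rng.normal(scale=np.sqrt(variance), size=(n, p))
        return LabeledDataset(X, y)

    return draw(n_train), draw(n_test)


def random_functional_graph(n: int, seed=0) -> np.ndarray:
    """Uniform random successor map on ``n`` vertices with no self-loops.

    Returns an ``(n,)`` int array ``succ`` with ``succ[i] != i`` — the
    out-degree-one digraph used as a test harness for the cycle census and
    partition-function oracles.
    """
    if n < 2:
        raise ValueError("need at least two vertices")
    rng = np.random.default_rng(seed)
    offsets = rng.integers(1, n, size=n)  # shift by 1..n-1 avoids self-loops
    return (np.arange(n) + offsets) % n
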