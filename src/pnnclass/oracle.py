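"""Brute-force and algebraic reference implementations for tiny instances.

Everything here is exponential in ``n`` by construction and exists to certify
the fast closed-form path on small problems:

* exhaustive ``O(L^n)`` summation of nonlocal and joint (all-k-neighbors)
  normalizing constants;
* the correspondence between the joint model's exponent ``T(y)`` and graph
  cuts — for binary labels, ``cut_size(y) = (1/2) sum_ij b_ij - T(y)`` where
  ``B = A + A^T`` is the weighted adjacency matrix of the k-neighborhood
  graph.  Determining the coefficient ``d_t = #{y : T(y) = t}`` for every
  ``t`` answers every max-cut decision question about that graph, which is
  why no polynomial-time exact summation of the joint constant is expected;
* recovery of the ``d_t`` from evaluations of ``Z`` as a polynomial in
  ``z = e^{beta/k}`` (Vandermonde interpolation);
* an exact, seeded sampler from a nonlocal model by total enumeration;
* an independent cycle counter based on successor iteration, used to
  cross-check the walk-stack counter in :mod:`pnnclass.cycles`.

All entry points refuse instances larger than a hard guard instead of
silently running for hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CucalaInstance",
    "CutEvaluation",
    "enumerate_labelings",
    "brute_force_Z_nonlocal",
    "brute_force_Z_cucala",
    "brute_force_T_moments",
    "cut_identity_check",
    "coefficients_by_enumeration",
    "coefficients_by_interpolation",
    "exact_sampler_nonlocal",
    "count_cycles_by_iteration",
]

_MAX_STATES = 2**20  # refuse enumerations beyond ~1M label vectors
_MAX_N = 14


def _guard(n: int, L: int) -> None:
    if n > _MAX_N or L**n > _MAX_STATES:
        raise ValueError(
            f"enumeration over L^n = {L}^{n} label vectors refused "
            f"(guard: n <= {_MAX_N} and L^n <= {_MAX_STATES})"
        )


def enumerate_labelings(n: int, L: int) -> np.ndarray:
    """All ``L^n`` label vectors as an ``(L^n, n)`` int8 array (guarded)."""
    _guard(n, L)
    idx = np.arange(L**n)
    powers = L ** np.arange(n)
    return ((idx[:, None] // powers) % L).astype(np.int8)


@dataclass(frozen=True)
class CucalaInstance:
    """A tiny joint-model instance: all-k-neighbors interactions.

    The joint model couples each unit with *all* of its k nearest neighbors:
    ``p(y) ∝ exp((beta/k) * T(y))`` with
    ``T(y) = sum_i sum_{r<=k} I(y_i = y_{[i]_r})``.

    Attributes
    ----------
    brackets : numpy.ndarray of shape (n, n-1)
        Neighbor brackets (0-based indices).
    k : int
        Neighborhood size.
    beta : float
        Interaction strength, >= 0.
    L : int
        Number of class labels.
    A : numpy.ndarray
        0/1 matrix, ``A[i, j] = 1`` iff j is among i's k nearest neighbors.
    B : numpy.ndarray
        ``A + A^T``; symmetric with entries in {0, 1, 2}, zero diagonal.
    z : float
        ``e^{beta/k}``, the variable in which Z is a polynomial.
    """

    brackets: np.ndarray
    k: int
    beta: float = 0.0
    L: int = 2
    A: np.ndarray = field(init=False)
    B: np.ndarray = field(init=False)
    z: float = field(init=False)

    def __post_init__(self):
        brackets = np.asarray(self.brackets, dtype=np.intp)
        object.__setattr__(self, "brackets", brackets)
        n = brackets.shape[0]
        if not 1 <= self.k <= n - 1:
            raise ValueError(f"k={self.k} out of range [1, {n - 1}]")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        A = np.zeros((n, n), dtype=np.intp)
        rows = np.repeat(np.arange(n), self.k)
        A[rows, brackets[:, : self.k].ravel()] = 1
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", A + A.T)
        object.__setattr__(self, "z", float(np.exp(self.beta / self.k)))

    @property
    def n(self) -> int:
        return self.brackets.shape[0]

    def T_of(self, y) -> int:
        """Exponent statistic ``T(y)`` for one label vector."""
        y = np.asarray(y)
        succ = self.brackets[:, : self.k]
        return int((y[:, None] == y[succ]).sum())


@dataclass(frozen=True)
class CutEvaluation:
    """Joint statistic and cut size of one binary labeling, with the identity checked."""

    y: np.ndarray
    T: int
    cut_size: int


def brute_force_Z_nonlocal(brackets, r: int, beta: float, L: int) -> float:
    """Exhaustive ``sum_y exp(beta * T_r(y))`` over all ``L^n`` labelings."""
    brackets = np.asarray(brackets, dtype=np.intp)
    n = brackets.shape[0]
    labels = enumerate_labelings(n, L)
    succ = brackets[:, r - 1]
    T = (labels == labels[:, succ]).sum(axis=1)
    return float(np.exp(beta * T).sum())


def brute_force_Z_cucala(instance: CucalaInstance) -> float:
    """Exhaustive normalizing constant of the joint all-k-neighbors model."""
    labels = enumerate_labelings(instance.n, instance.L)
    succ = instance.brackets[:, : instance.k]
    T = (labels[:, :, None] == labels[:, succ]).sum(axis=(1, 2))
    return float(np.exp((instance.beta / instance.k) * T).sum())


def brute_force_T_moments(brackets, r: int, beta: float, L: int) -> tuple[float, float]:
    """Exact mean and variance of ``T_r`` under the rank-r nonlocal model."""
    brackets = np.asarray(brackets, dtype=np.intp)
    n = brackets.shape[0]
    labels = enumerate_labelings(n, L)
    succ = brackets[:, r - 1]
    T = (labels == labels[:, succ]).sum(axis=1).astype(float)
    w = np.exp(beta * T)
    w /= w.sum()
    mean = float(w @ T)
    return mean, float(w @ (T - mean) ** 2)


def cut_identity_check(instance: CucalaInstance, y) -> CutEvaluation:
    """Verify ``cut_size(y) = (1/2) sum_ij b_ij - T(y)`` for one binary labeling.

    The cut partitions vertices by label; its size sums ``b_ij`` over
    discordant pairs.  Both sides are computed independently and the identity
    is asserted.
    """
    y = np.asarray(y)
    if instance.L != 2 or not np.isin(y, (0, 1)).all():
        raise ValueError("cut correspondence requires binary labels in {0, 1}")
    T = instance.T_of(y)
    discordant = y[:, None] != y[None, :]
    cut_size = int(instance.B[discordant].sum() // 2)
    if cut_size != instance.B.sum() // 2 - T:
        raise AssertionError(
            f"cut identity violated: cut={cut_size}, "
            f"half-weight={instance.B.sum() // 2}, T={T}"
        )
    return CutEvaluation(y=y, T=T, cut_size=cut_size)


def coefficients_by_enumeration(instance: CucalaInstance) -> np.ndarray:
    """Coefficients ``d_t = #{y in {0,1}^n : T(y) = t}`` for t = 0..n*k.

    These are the coefficients of ``Z`` as a polynomial in ``z = e^{beta/k}``;
    they also count the cuts of the k-neighborhood graph of every size.
    """
    if instance.L != 2:
        raise ValueError("polynomial representation is defined for binary labels")
    n, k = instance.n, instance.k
    labels = enumerate_labelings(n, 2)
    succ = instance.brackets[:, :k]
    T = (labels[:, :, None] == labels[:, succ]).sum(axis=(1, 2))
    return np.bincount(T, minlength=n * k + 1).astype(np.intp)


def _Z_at_integer_z(instance: CucalaInstance, z: int) -> int:
    """Exact integer evaluation of ``Z(z) = sum_y z^{T(y)}`` by direct summation."""
    labels = enumerate_labelings(instance.n, 2)
    succ = instance.brackets[:, : instance.k]
    T = (labels[:, :, None] == labels[:, succ]).sum(axis=(1, 2))
    return sum(z ** int(t) for t in T)


def coefficients_by_interpolation(instance: CucalaInstance, z_values=None) -> np.ndarray:
    """Recover the ``d_t`` from ``n*k + 1`` evaluations of ``Z``.

    ``Z(z) = sum_t d_t z^t`` is a degree-``n*k`` polynomial in
    ``z = e^{beta/k}``, so its coefficients are determined by evaluations at
    ``n*k + 1`` distinct points — this is why a polynomial-time exact summation
    of Z would count all cuts.

    With the default nodes (``z = 1, 2, ..., n*k + 1``) every ``Z(z)`` is
    evaluated in exact integer arithmetic and the Vandermonde system is
    solved over the rationals, so the recovered coefficients are exact at any
    degree.  User-supplied float nodes fall back to a double-precision solve
    with integer rounding and a residual check, which is reliable only for
    small degrees.
    """
    if instance.L != 2:
        raise ValueError("polynomial representation is defined for binary labels")
    n, k = instance.n, instance.k
    if n > 12:
        raise ValueError(f"interpolation guard: n <= 12, got {n}")
    deg = n * k
    if z_values is None:
        from fractions import Fraction

        nodes = list(range(1, deg + 2))
        zvals = [_Z_at_integer_z(instance, z) for z in nodes]
        # exact Gaussian elimination on the Vandermonde system V d = Z
        V = [[Fraction(z**t) for t in range(deg + 1)] for z in nodes]
        rhs = [Fraction(v) for v in zvals]
        for col in range(deg + 1):
            piv = next(i for i in range(col, deg + 1) if V[i][col] != 0)
            V[col], V[piv] = V[piv], V[col]
            rhs[col], rhs[piv] = rhs[piv], rhs[col]
            inv = 1 / V[col][col]
            V[col] = [v * inv for v in V[col]]
            rhs[col] *= inv
            for i in range(deg + 1):
                if i != col and V[i][col] != 0:
                    f = V[i][col]
                    V[i] = [a - f * b for a, b in zip(V[i], V[col])]
                    rhs[i] -= f * rhs[col]
        d = np.array([int(v) for v in rhs], dtype=np.intp)
        if any(v.denominator != 1 for v in rhs):
            raise ArithmeticError("exact interpolation produced non-integer counts")
        return d
    z_values = np.asarray(z_values, dtype=float)
    if z_values.shape[0] != deg + 1 or len(np.unique(z_values)) != deg + 1:
        raise ValueError(f"need {deg + 1} distinct evaluation points")
    if (z_values <= 0).any():
        raise ValueError("evaluation points must be positive (z = e^(beta/k))")
    zvals = np.array(
        [
            brute_force_Z_cucala(
                CucalaInstance(instance.brackets, k, beta=float(k * np.log(z)), L=2)
            )
            for z in z_values
        ]
    )
    V = np.vander(z_values, N=deg + 1, increasing=True)
    d = np.linalg.solve(V, zvals)
    rounded = np.rint(d)
    if np.abs(d - rounded).max() > 1e-6 * max(1.0, np.abs(rounded).max()):
        raise ArithmeticError(
            "Vandermonde system too ill-conditioned: residual after rounding "
            f"{np.abs(d - rounded).max():.3g}"
        )
    return rounded.astype(np.intp)


def exact_sampler_nonlocal(brackets, r: int, beta: float, L: int, size: int, seed) -> np.ndarray:
    """Exact i.i.d. draws from the rank-r nonlocal model by total enumeration.

    Returns an ``(size, n)`` array of label vectors (labels 0..L-1); guarded
    to ``n <= 12``.
    """
    brackets = np.asarray(brackets, dtype=np.intp)
    n = brackets.shape[0]
    if n > 12:
        raise ValueError(f"exact sampler guard: n <= 12, got {n}")
    labels = enumerate_labelings(n, L)
    succ = brackets[:, r - 1]
    T = (labels == labels[:, succ]).sum(axis=1)
    logw = beta * T.astype(float)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    rng = np.random.default_rng(seed)
    picks = rng.choice(labels.shape[0], size=size, p=w)
    return labels[picks].astype(np.intp)


def count_cycles_by_iteration(succ) -> np.ndarray:
    """Independent cycle census of a functional graph via successor iteration.

    From every vertex, iterate the successor map ``n`` times to land on the
    component's cycle, then walk the cycle to measure its length; distinct
    cycles are identified by their minimal vertex.  Deliberately a different
    algorithm from the walk-stack counter it cross-checks.
    """
    succ = np.asarray(succ, dtype=np.intp)
    n = succ.shape[0]
    counts = np.zeros(n + 1, dtype=np.intp)
    seen_cycle_reps: set[int] = set()
    for start in range(n):
        i = start
        for _ in range(n):
            i = int(succ[i])
        # i is now on a cycle; walk it
        cycle = [i]
        j = int(succ[i])
        while j != i:
            cycle.append(j)
            j = int(succ[j])
        rep = min(cycle)
        if rep not in seen_cycle_reps:
            seen_cycle_reps.add(rep)
            counts[len(cycle)] += 1
    return counts
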