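"""Exact likelihood machinery for the rank-r nonlocal label models.

The rank-``r`` nonlocal model places a Boltzmann-type distribution on label
vectors ``y`` in ``{1..L}^n``:

    p_r(y | beta_r)  =  exp(beta_r * T_r(y)) / Z_r(beta_r),
    T_r(y)           =  sum_i  I(y_i = y_{[i]_r}),

where ``[i]_r`` is unit ``i``'s ``r``-th nearest neighbor.  Because each unit
interacts with exactly one other unit, the rank-``r`` interaction digraph is a
functional graph and the normalizing constant factorizes over its weakly
connected components.  Summing out the tree vertices of a component yields a
factor ``(e^b + L - 1)`` each; the remaining simple cycle of size ``m`` sums
to the trace of the ``m``-th power of the L x L transfer matrix
``S_{a,b} = exp(b * I(a=b))``, whose eigenvalues are ``e^b - 1`` (multiplicity
L-1) and ``e^b + L - 1``.  With ``c_m`` simple cycles of size ``m``:

    Z_r(b) = (e^b + L - 1)^(n - sum_m m c_m)
             * prod_m [ (e^b + L - 1)^m + (L-1)(e^b - 1)^m ]^(c_m)

computable exactly in O(n) once the cycle census is known.  All arithmetic is
done in log space; the two-term cycle factor uses log-sum-exp.

``T_r`` is the sufficient statistic, so the log-likelihood
``b*T_r - log Z_r(b)`` is concave in ``b`` and the MLE is a one-dimensional
bounded maximization.  The score at 0 is ``T_r - n/L``; whenever
``T_r <= n/L`` the constrained MLE is exactly 0.  When ``T_r`` is at (or very
near) its maximum the unconstrained MLE diverges; estimates are clipped at
``beta_max`` and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "NonlocalFit",
    "sufficient_statistic",
    "log_partition",
    "log_likelihood",
    "fit_beta",
    "transfer_matrix_eigenvalues",
    "DEFAULT_BETA_MAX",
]

DEFAULT_BETA_MAX = 30.0
_CLIP_TOL = 1e-5


@dataclass(frozen=True)
class NonlocalFit:
    """Maximum-likelihood fit of one rank-r nonlocal model.

    Attributes
    ----------
    r : int
        Neighbor rank of the model.
    beta_hat : float
        Constrained MLE of the interaction strength, in [0, beta_max].
    T : int
        Sufficient statistic: number of units whose label matches their
        r-th neighbor's label.
    log_Z : float
        Log normalizing constant at ``beta_hat``.
    converged : bool
        Whether the scalar optimizer reported success (boundary solutions
        at 0 are exact and always converged).
    clipped : bool
        True when the maximizer hit the ``beta_max`` bound (unbounded MLE).
    """

    r: int
    beta_hat: float
    T: int
    log_Z: float
    converged: bool
    clipped: bool


def transfer_matrix_eigenvalues(beta: float, L: int) -> tuple[float, float]:
    """Eigenvalues of the L x L transfer matrix ``exp(beta I(a=b))``.

    Returns ``(lambda_bulk, lambda_top) = (e^beta - 1, e^beta + L - 1)``;
    the bulk eigenvalue has multiplicity ``L - 1``.
    """
    eb = np.exp(beta)
    return eb - 1.0, eb + L - 1.0


def sufficient_statistic(labels, brackets, r: int) -> int:
    """Number of units whose label equals their r-th nearest neighbor's label."""
    labels = np.asarray(labels)
    brackets = np.asarray(brackets, dtype=np.intp)
    n = labels.shape[0]
    if not 1 <= r <= n - 1:
        raise ValueError(f"rank r={r} out of range [1, {n - 1}]")
    return int(np.count_nonzero(labels == labels[brackets[:, r - 1]]))


def _log_eigs(beta: float, L: int) -> tuple[float, float]:
    # log(e^b + L - 1) and log(e^b - 1), the latter -inf at b = 0
    log_top = float(np.logaddexp(beta, np.log(L - 1)))
    if beta > 0:
        log_bulk = beta + np.log1p(-np.exp(-beta))
    else:
        log_bulk = -np.inf
    return log_top, log_bulk


def log_partition(beta: float, L: int, n: int, counts) -> float:
    """Log normalizing constant ``log Z_r(beta)`` of a rank-r nonlocal model.

    Parameters
    ----------
    beta : float
        Interaction strength, ``beta >= 0``.
    L : int
        Number of class labels, ``L >= 2``.
    n : int
        Number of sample units.
    counts : array-like
        Cycle census for this rank: ``counts[m]`` is the number of simple
        cycles of size ``m`` (entries 0 and 1 must be zero).

    Returns
    -------
    float
        ``log Z_r(beta)``; equals ``n * log(L)`` at ``beta = 0``.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    if L < 2:
        raise ValueError(f"need at least two class labels, got L={L}")
    counts = np.asarray(counts)
    if counts[:2].any():
        raise ValueError("cycles of size 0 or 1 cannot occur")
    sizes = np.flatnonzero(counts)
    cyc_vertices = int((sizes * counts[sizes]).sum())
    if cyc_vertices > n:
        raise ValueError("cycle census inconsistent with n: sum m*c_m > n")
    log_top, log_bulk = _log_eigs(beta, L)
    log_L1 = np.log(L - 1)
    total = (n - cyc_vertices) * log_top
    for m in sizes:
        # Tr(S^m) = top^m + (L-1) * bulk^m, in log space
        log_tr = np.logaddexp(m * log_top, log_L1 + m * log_bulk)
        total += counts[m] * log_tr
    return float(total)


def log_likelihood(beta: float, T: int, L: int, n: int, counts) -> float:
    """Log-likelihood ``beta * T - log Z_r(beta)`` of a rank-r model."""
    return beta * T - log_partition(beta, L, n, counts)


def fit_beta(
    T: int,
    L: int,
    n: int,
    counts,
    r: int = 0,
    beta_max: float = DEFAULT_BETA_MAX,
    xatol: float = 1e-8,
) -> NonlocalFit:
    """Constrained MLE of the interaction strength of one nonlocal model.

    Maximizes the concave log-likelihood over ``[0, beta_max]`` by bounded
    scalar search.  The score at 0 is ``T - n/L``, so ``beta_hat = 0`` exactly
    whenever ``T <= n/L``; a maximizer within tolerance of ``beta_max`` is
    snapped to the bound and flagged ``clipped``.
    """
    if not 0 <= T <= n:
        raise ValueError(f"sufficient statistic T={T} out of range [0, {n}]")
    if T * L <= n:  # score at 0 is T - n/L <= 0: boundary solution
        return NonlocalFit(
            r=r,
            beta_hat=0.0,
            T=int(T),
            log_Z=log_partition(0.0, L, n, counts),
            converged=True,
            clipped=False,
        )
    if T == n:  # E_beta[T] < n for every finite beta: the MLE is unbounded
        return NonlocalFit(
            r=r,
            beta_hat=float(beta_max),
            T=int(T),
            log_Z=log_partition(float(beta_max), L, n, counts),
            converged=True,
            clipped=True,
        )
    res = minimize_scalar(
        lambda b: -(b * T - log_partition(b, L, n, counts)),
        bounds=(0.0, beta_max),
        method="bounded",
        options={"xatol": xatol},
    )
    beta_hat = float(res.x)
    clipped = beta_hat >= beta_max - max(_CLIP_TOL, 10 * xatol)
    if clipped:
        beta_hat = float(beta_max)
    return NonlocalFit(
        r=r,
        beta_hat=beta_hat,
        T=int(T),
        log_Z=log_partition(beta_hat, L, n, counts),
        converged=bool(res.success),
        clipped=clipped,
    )
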