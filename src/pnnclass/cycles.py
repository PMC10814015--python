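"""Cycle counting on rank-r neighbor digraphs.

For each rank ``r`` the map ``i -> brackets[i, r-1]`` is a *functional graph*:
every vertex has outdegree exactly one.  Each weakly connected component of
such a graph contains exactly one simple (directed) cycle, with the remaining
vertices hanging off the cycle in trees.  The number ``c_m(r)`` of simple
cycles of size ``m`` in the rank-``r`` graph is the only structural input the
partition function of the rank-``r`` label model needs.

The counter below walks each component once with a visited set and an explicit
walk stack, popping the stack to locate the cycle entry point; total work is
O(n) per rank and O(n^2) for all ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CycleCounts", "count_simple_cycles", "cycle_counts_for_successor",
           "component_decomposition"]


@dataclass(frozen=True)
class CycleCounts:
    """Simple-cycle census of every rank-r neighbor digraph.

    Attributes
    ----------
    c : numpy.ndarray of shape (n-1, n+1)
        ``c[r-1, m]`` is the number of simple cycles of size ``m`` in the
        rank-``r`` digraph.  Columns 0 and 1 are always zero (no unit is its
        own neighbor, so there are no self-loops).
    n : int
        Number of vertices (sample units).
    """

    c: np.ndarray
    n: int = field(default=0)

    def for_rank(self, r: int) -> np.ndarray:
        """Counts ``c_m`` for one rank, as a vector indexed by cycle size m."""
        if not 1 <= r <= self.c.shape[0]:
            raise ValueError(f"rank r={r} out of range [1, {self.c.shape[0]}]")
        return self.c[r - 1]


def cycle_counts_for_successor(succ) -> np.ndarray:
    """Count simple cycles of each size in one functional graph.

    Parameters
    ----------
    succ : array-like of int, shape (n,)
        Successor map; ``succ[i]`` is the unique out-neighbor of vertex ``i``.

    Returns
    -------
    numpy.ndarray of shape (n+1,)
        Entry ``m`` is the number of simple cycles of size ``m``.
    """
    succ = np.asarray(succ, dtype=np.intp)
    n = succ.shape[0]
    counts = np.zeros(n + 1, dtype=np.intp)
    visited = np.zeros(n, dtype=bool)
    for j in range(n):
        if visited[j]:
            continue
        walk: list[int] = []
        i = j
        while not visited[i]:
            visited[i] = True
            walk.append(i)
            i = succ[i]
        # i is the first revisited vertex; if it lies on the current walk the
        # popped suffix from i to the walk's top is a new simple cycle
        m = 1
        while walk:
            top = walk.pop()
            if top == i:
                counts[m] += 1
                break
            m += 1
    return counts


def count_simple_cycles(brackets) -> CycleCounts:
    """Cycle census of the rank-r digraph for every rank r = 1..n-1."""
    brackets = np.asarray(brackets, dtype=np.intp)
    n = brackets.shape[0]
    c = np.zeros((n - 1, n + 1), dtype=np.intp)
    for r in range(1, n):
        c[r - 1] = cycle_counts_for_successor(brackets[:, r - 1])
    return CycleCounts(c=c, n=n)


def component_decomposition(brackets, r: int) -> list[set[int]]:
    """Weakly connected components of the rank-``r`` neighbor digraph.

    Each component contains exactly one simple cycle, so the number of
    components equals the total cycle count of the rank-``r`` graph.
    """
    brackets = np.asarray(brackets, dtype=np.intp)
    n = brackets.shape[0]
    if not 1 <= r <= n - 1:
        raise ValueError(f"rank r={r} out of range [1, {n - 1}]")
    succ = brackets[:, r - 1]
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        ra, rb = find(i), find(int(succ[i]))
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [groups[k] for k in sorted(groups)]
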