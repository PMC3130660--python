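"""Exact maximum-clique search on small dense graphs.

Branch-and-bound in the style of Östergård's algorithm: vertices are
processed in a fixed order, iterating the start vertex from last to first
while recording ``c[i]``, the maximum clique size of the subgraph induced
by vertices ``i..n-1``.  ``c[i]`` then serves as an incremental bound when
earlier start vertices are explored.  Two entry points are provided: one
that enumerates *all* maximum cliques (the search continues through ties
instead of exiting at the first optimum) and a faster single-solution
path that accepts a lower bound.

Adjacency is held as one Python-int bitmask per vertex, which makes
candidate-set intersection a single ``&``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = ["SimpleGraph", "max_cliques_all", "max_clique_one"]


@dataclass
class SimpleGraph:
    """Undirected simple graph over vertices ``0..n-1`` as bitmask rows."""

    n: int
    adj: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.adj:
            self.adj = [0] * self.n
        if len(self.adj) != self.n:
            raise ValueError("adjacency length != vertex count")
        for u, bits in enumerate(self.adj):
            if (bits >> u) & 1:
                raise ValueError(f"self-loop at vertex {u}")
            if bits >> self.n:
                raise ValueError(f"adjacency bits beyond vertex count at {u}")
        for u in range(self.n):
            for v in range(u + 1, self.n):
                if ((self.adj[u] >> v) & 1) != ((self.adj[v] >> u) & 1):
                    raise ValueError(f"asymmetric adjacency between {u} and {v}")

    @classmethod
    def from_edges(cls, n: int, edges: list[tuple[int, int]]) -> "SimpleGraph":
        adj = [0] * n
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
            adj[u] |= 1 << v
            adj[v] |= 1 << u
        return cls(n, adj)

    def add_edge(self, u: int, v: int) -> None:
        if u == v:
            raise ValueError("self-loop")
        self.adj[u] |= 1 << v
        self.adj[v] |= 1 << u

    def has_edge(self, u: int, v: int) -> bool:
        return bool((self.adj[u] >> v) & 1)


def _lowest_bit_index(bits: int) -> int:
    return (bits & -bits).bit_length() - 1


def max_cliques_all(g: SimpleGraph) -> tuple[int, list[frozenset[int]]]:
    """Size of the maximum clique plus *every* clique of that size.

    Returns ``(0, [])`` for the empty graph.  Cliques are reported exactly
    once each, as frozensets, in sorted deterministic order.  Bound checks
    use strict inequality so branches that can only *tie* the incumbent
    are still explored and their cliques collected.
    """
    n = g.n
    if n == 0:
        return 0, []
    adj = g.adj
    c = [0] * n
    best = 0
    collected: list[list[int]] = []
    current: list[int] = []

    def expand(cand: int, size: int) -> None:
        nonlocal best
        if cand == 0:
            if size > best:
                best = size
                collected.clear()
            if size == best:
                collected.append(list(current))
            return
        while cand:
            if size + cand.bit_count() < best:
                return
            v = _lowest_bit_index(cand)
            if size + c[v] < best:
                return
            cand &= ~(1 << v)
            current.append(v)
            expand(cand & adj[v], size + 1)
            current.pop()

    for i in range(n - 1, -1, -1):
        current.append(i)
        tail = ((1 << n) - 1) ^ ((1 << i) - 1)  # vertices i..n-1
        expand(adj[i] & tail & ~(1 << i), 1)
        current.pop()
        c[i] = best

    cliques = sorted(set(frozenset(cl) for cl in collected), key=sorted)
    return best, cliques


def max_clique_one(
    g: SimpleGraph, lower_bound: int = 0
) -> Optional[tuple[int, frozenset[int]]]:
    """One maximum clique, provided its size reaches ``lower_bound``.

    Returns ``None`` ("no improvement") when the maximum clique is smaller
    than ``lower_bound`` — in that regime the bound is used for aggressive
    pruning, so the true size is not necessarily determined.  When a
    result is returned its size is the true maximum.
    """
    if lower_bound < 0:
        raise ValueError("lower_bound must be >= 0")
    n = g.n
    if n == 0:
        return (0, frozenset()) if lower_bound == 0 else None
    adj = g.adj
    c = [0] * n
    # prune at <= best: cliques of size <= lower_bound - 1 are never recorded
    best = max(lower_bound - 1, 0)
    best_clique: Optional[list[int]] = None
    current: list[int] = []
    found = False

    def expand(cand: int, size: int) -> None:
        nonlocal best, best_clique, found
        if cand == 0:
            if size > best:
                best = size
                best_clique = list(current)
                found = True
            return
        while cand:
            if size + cand.bit_count() <= best:
                return
            v = _lowest_bit_index(cand)
            if size + c[v] <= best:
                return
            cand &= ~(1 << v)
            current.append(v)
            expand(cand & adj[v], size + 1)
            current.pop()
            if found:
                return

    for i in range(n - 1, -1, -1):
        found = False
        current.append(i)
        tail = ((1 << n) - 1) ^ ((1 << i) - 1)
        expand(adj[i] & tail & ~(1 << i), 1)
        current.pop()
        c[i] = best

    if best_clique is None:
        return None
    return best, frozenset(best_clique)
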