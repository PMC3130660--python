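"""Ratios of paired distances, the tolerance model, and the compatibility graph.

Two candidate protein pairings ``(a_u, b_x)`` and ``(a_v, b_y)`` are scored
by their ratio of paired distances (RPD) ``d_A(a_u, a_v) / d_B(b_x, b_y)``.
A tolerance ``alpha`` in [0, 1] controls how far two RPDs may diverge while
still being considered mutually *compatible*: 0 demands exact equality, 1
imposes no restriction.  The compatibility graph has one vertex per
admissible pairing and an RPD-labelled edge between every two pairings that
could coexist in a match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, NamedTuple, Optional

import numpy as np

from .matrix_io import DistanceMatrix

__all__ = [
    "Tolerance",
    "Vertex",
    "CompatibilityGraph",
    "delta_factor",
    "compatible",
    "forward_compatible",
    "rpd",
    "build_compatibility_graph",
]


def delta_factor(alpha: float) -> float:
    """Expansion factor ``delta`` derived from ``alpha``.

    Two RPDs are compatible when the larger is at most ``delta`` times the
    smaller.  ``delta = 1 / (1 - alpha)`` for ``alpha`` in [0, 1), and
    ``+inf`` at ``alpha = 1`` so no restriction applies.  This mapping is
    isolated here so an alternative (e.g. ``(1 + alpha) / (1 - alpha)``)
    is a one-line change.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if alpha == 1.0:
        return math.inf
    return 1.0 / (1.0 - alpha)


@dataclass(frozen=True)
class Tolerance:
    """Tolerance parameter ``alpha`` with its derived expansion factor."""

    alpha: float

    def __post_init__(self) -> None:
        delta_factor(self.alpha)  # range check

    @property
    def delta(self) -> float:
        return delta_factor(self.alpha)


def compatible(r1: float, r2: float, tol: Tolerance) -> bool:
    """Whether two RPDs are mutually compatible: ``max <= delta * min``.

    Symmetric in its arguments; always true at ``alpha = 1``.
    """
    if r1 <= 0.0 or r2 <= 0.0:
        raise ValueError("RPDs must be positive")
    if tol.alpha == 1.0:
        return True
    lo, hi = (r1, r2) if r1 <= r2 else (r2, r1)
    return hi <= tol.delta * lo


def forward_compatible(r_min: float, r: float, tol: Tolerance) -> bool:
    """One-sided compatibility: ``r_min <= r <= delta * r_min``.

    Antisymmetric except at equality; implies :func:`compatible`.
    """
    if r_min <= 0.0 or r <= 0.0:
        raise ValueError("RPDs must be positive")
    if r < r_min:
        return False
    return tol.alpha == 1.0 or r <= tol.delta * r_min


class Vertex(NamedTuple):
    """One candidate A-to-B protein pairing: a cell of the pairing grid."""

    a_index: int
    b_index: int


def rpd(
    mat_a: DistanceMatrix, mat_b: DistanceMatrix, u: Vertex, v: Vertex
) -> Optional[float]:
    """RPD between pairings ``u`` and ``v``, or ``None`` when undefined.

    The ratio is ``d_A(a_u, a_v) / d_B(b_u, b_v)``; it is undefined (no
    edge) when either distance is zero, which includes ``u`` and ``v``
    sharing a row or a column.
    """
    d_a = mat_a.distance(u.a_index, v.a_index)
    d_b = mat_b.distance(u.b_index, v.b_index)
    if d_a == 0.0 or d_b == 0.0:
        return None
    return d_a / d_b


class CompatibilityGraph:
    """Vertices are admissible pairings; edges carry RPD labels.

    Vertices are numbered by ``(a_index, b_index)`` lexicographic order —
    the row-major pairing grid — which fixes the total order the solver's
    index-based deduplication rules rely on.  Adjacency is kept as one
    bitmask per vertex; RPDs as a dense matrix with NaN marking non-edges.
    """

    def __init__(
        self,
        mat_a: DistanceMatrix,
        mat_b: DistanceMatrix,
        vertices: list[Vertex],
        rpd_matrix: np.ndarray,
        adj_bits: list[int],
    ) -> None:
        self.mat_a = mat_a
        self.mat_b = mat_b
        self.vertices = vertices
        self._rpd = rpd_matrix
        self._adj = adj_bits

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return sum(a.bit_count() for a in self._adj) // 2

    def has_edge(self, u: int, v: int) -> bool:
        return bool((self._adj[u] >> v) & 1)

    def rpd_edge(self, u: int, v: int) -> Optional[float]:
        """RPD label of edge (u, v), or None when there is no edge."""
        r = self._rpd[u, v]
        return None if math.isnan(r) else float(r)

    def adjacency_bits(self, u: int) -> int:
        return self._adj[u]

    def neighbors(self, u: int) -> list[int]:
        bits = self._adj[u]
        out = []
        while bits:
            low = bits & -bits
            out.append(low.bit_length() - 1)
            bits ^= low
        return out

    def iter_edges(self) -> Iterator[tuple[int, int, float]]:
        for u in range(self.n_vertices):
            for v in self.neighbors(u):
                if v > u:
                    yield u, v, float(self._rpd[u, v])

    def vertex_labels(self, u: int) -> tuple[str, str]:
        vert = self.vertices[u]
        return self.mat_a.labels[vert.a_index], self.mat_b.labels[vert.b_index]


def build_compatibility_graph(
    mat_a: DistanceMatrix, mat_b: DistanceMatrix
) -> CompatibilityGraph:
    """Construct the compatibility graph for two families.

    The vertex set contains every ``(a, b)`` pairing; when *both* matrices
    carry species tags, only same-species pairings are admitted.  An edge
    joins every two vertices that share no row or column and whose A and B
    distances are both nonzero; it is labelled with the RPD.
    """
    restrict = mat_a.species is not None and mat_b.species is not None
    vertices: list[Vertex] = []
    for i in range(mat_a.n):
        for j in range(mat_b.n):
            if restrict and mat_a.species[i] != mat_b.species[j]:
                continue
            vertices.append(Vertex(i, j))

    n = len(vertices)
    rpd_matrix = np.full((n, n), np.nan)
    adj = [0] * n
    a_idx = np.array([v.a_index for v in vertices], dtype=int)
    b_idx = np.array([v.b_index for v in vertices], dtype=int)
    if n:
        d_a = mat_a.values[np.ix_(a_idx, a_idx)]
        d_b = mat_b.values[np.ix_(b_idx, b_idx)]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = d_a / d_b
        ok = (d_a > 0.0) & (d_b > 0.0)
        # same row or column forces a zero distance, so `ok` already
        # excludes those pairs; keep the triangle only
        rpd_matrix[ok] = ratio[ok]
        for u in range(n):
            bits = 0
            for v in np.nonzero(ok[u])[0]:
                bits |= 1 << int(v)
            adj[u] = bits
    return CompatibilityGraph(mat_a, mat_b, vertices, rpd_matrix, adj)
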