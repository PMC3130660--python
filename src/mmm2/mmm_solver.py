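"""The exact coevolution sweep and the legacy triplet-based comparator.

A *match* is a set of one-to-one A-to-B pairings whose ratios of paired
distances are all pairwise compatible; its size is the coevolution score.
The solver turns every edge of the compatibility graph, in turn, into the
assumed minimum-RPD edge ``e_min`` of a candidate match and "works
backwards": every further vertex whose edges are forward-compatible with
``e_min`` can join, mutual compatibility being guaranteed by the
one-sidedness of forward-compatibility.  Each such subproblem is a
maximum-clique instance on a small subgraph ``H``.

Index-based rules (the ``j > i`` edge orientation and the ``k > i`` /
``x, y > i`` conditions on RPD ties with ``e_min``) ensure each maximum
match is produced exactly once across the sweep.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from .compat_core import CompatibilityGraph, Tolerance, Vertex, forward_compatible, compatible
from .max_clique import SimpleGraph, max_clique_one, max_cliques_all

__all__ = [
    "Match",
    "SolverResult",
    "solve",
    "is_match",
    "match_edge_count",
    "legacy_mmm_match_test",
]


@dataclass(frozen=True)
class Match:
    """A set of protein pairings forming a mutually compatible match."""

    pairs: frozenset[Vertex]

    @property
    def size(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[Vertex]:
        return sorted(self.pairs)

    def labels(self, g: CompatibilityGraph) -> list[tuple[str, str]]:
        out = []
        for v in self.sorted_pairs():
            out.append((g.mat_a.labels[v.a_index], g.mat_b.labels[v.b_index]))
        return out


@dataclass
class SolverResult:
    """Best match size (the coevolution score) plus the matches themselves.

    ``trivial`` flags scores below 3, where the match condition degenerates
    (no pair of RPDs exists to constrain) and downstream users typically
    filter.
    """

    score: int
    matches: list[Match]
    stats: dict = field(default_factory=dict)

    @property
    def trivial(self) -> bool:
        return self.score < 3

    def match_index_sets(self, g: CompatibilityGraph) -> set[frozenset[int]]:
        """Matches as frozensets of graph vertex indices (for comparisons)."""
        pos = {v: idx for idx, v in enumerate(g.vertices)}
        return {frozenset(pos[p] for p in m.pairs) for m in self.matches}


def _canonical_matches(
    g: CompatibilityGraph, index_sets: Iterable[frozenset[int]]
) -> list[Match]:
    matches = [Match(frozenset(g.vertices[i] for i in s)) for s in index_sets]
    return sorted(matches, key=lambda m: m.sorted_pairs())


def solve(
    g: CompatibilityGraph,
    tol: Tolerance,
    maxtrees: Literal["all", "one", 1] = "all",
) -> SolverResult:
    """Find the largest match(es) of the compatibility graph.

    Parameters
    ----------
    g
        Compatibility graph built by :mod:`mmm2.compat_core`.
    tol
        Tolerance in effect for RPD compatibility.
    maxtrees
        ``"all"`` enumerates every maximum match; ``"one"`` (or ``1``)
        returns a single maximum match, which permits much stronger
        pruning in the clique subproblems.

    Notes
    -----
    Per start vertex ``v_i`` the neighbours are sorted ascending by the
    RPD of their edge to ``v_i`` (ties by global vertex index).  For each
    neighbour ``v_j`` with global index ``j > i``, the edge ``(v_i, v_j)``
    becomes ``e_min``.  Candidates ``v_k`` strictly ahead of ``v_j`` in
    the sorted list join ``H`` when both their edges to ``v_i`` and
    ``v_j`` are forward-compatible with ``e_min``; the scan stops at the
    first ``v_k`` whose edge to ``v_i`` fails, which the sort makes final.
    RPD ties with ``e_min`` are admitted only for ``k > i`` (vertices) and
    ``x, y > i`` (edges of ``H``) to avoid duplicate discoveries.  A
    subproblem whose ``|H| + 2`` cannot beat the incumbent score is
    skipped.  The maximum cliques of ``H``, each extended by ``v_i`` and
    ``v_j``, are the candidate matches.
    """
    one_mode = maxtrees in ("one", 1, "1")
    if not one_mode and maxtrees != "all":
        raise ValueError(f"maxtrees must be 'all' or 'one', got {maxtrees!r}")

    n = g.n_vertices
    stats = {
        "vertices": n,
        "edges": g.n_edges,
        "subproblems": 0,
        "pruned": 0,
    }
    if n == 0:
        return SolverResult(0, [], stats)

    rpd_of = g.rpd_edge
    # neighbour lists sorted ascending by RPD to the start vertex, ties by
    # global index (a stable total order the dedup rules presuppose)
    best = 0
    found: set[frozenset[int]] = set()

    for i in range(n):
        nbrs = sorted(g.neighbors(i), key=lambda k: (rpd_of(i, k), k))
        r_i = [rpd_of(i, k) for k in nbrs]
        for pos_j, j in enumerate(nbrs):
            if j <= i:
                continue
            e_min = r_i[pos_j]
            # Step 3: vertex set of H from candidates ahead of v_j
            h_verts: list[int] = []
            for pos_k in range(pos_j + 1, len(nbrs)):
                k = nbrs[pos_k]
                r_ik = r_i[pos_k]
                if not forward_compatible(e_min, r_ik, tol):
                    break  # sorted by r_ik: every later candidate fails too
                r_jk = rpd_of(j, k) if g.has_edge(j, k) else None
                if r_jk is None or not forward_compatible(e_min, r_jk, tol):
                    continue
                if (r_ik == e_min or r_jk == e_min) and k <= i:
                    continue
                h_verts.append(k)

            h = len(h_verts)
            if one_mode:
                if h + 2 <= best:
                    stats["pruned"] += 1
                    continue
            else:
                if h + 2 < best:
                    stats["pruned"] += 1
                    continue

            # Step 4: edge set of H
            sub = SimpleGraph(h)
            for x in range(h):
                vx = h_verts[x]
                for y in range(x + 1, h):
                    vy = h_verts[y]
                    if not g.has_edge(vx, vy):
                        continue
                    r_xy = rpd_of(vx, vy)
                    if not forward_compatible(e_min, r_xy, tol):
                        continue
                    if r_xy == e_min and not (vx > i and vy > i):
                        continue
                    sub.add_edge(x, y)

            if one_mode:
                if h == 0:
                    size = 2
                    if size > best:
                        best = size
                        found = {frozenset((i, j))}
                    continue
                stats["subproblems"] += 1
                res = max_clique_one(sub, lower_bound=max(best - 1, 0))
                if res is None:
                    continue
                csize, clique = res
                size = csize + 2
                if size > best:
                    best = size
                    members = frozenset(
                        {i, j} | {h_verts[x] for x in clique}
                    )
                    found = {members}
            else:
                if h == 0:
                    csize, cliques = 0, [frozenset()]
                else:
                    stats["subproblems"] += 1
                    csize, cliques = max_cliques_all(sub)
                size = csize + 2
                if size > best:
                    best = size
                    found = set()
                if size == best:
                    for cl in cliques:
                        found.add(frozenset({i, j} | {h_verts[x] for x in cl}))

    if best == 0:
        # no edges at all: any single pairing is the largest (trivial) match
        best = 1
        if one_mode:
            found = {frozenset((0,))}
        else:
            found = {frozenset((v,)) for v in range(n)}

    stats["score"] = best
    return SolverResult(best, _canonical_matches(g, found), stats)


def match_edge_count(g: CompatibilityGraph, members: Sequence[int]) -> int:
    """Number of compatibility-graph edges among ``members`` (vertex ids)."""
    return sum(
        1
        for u, v in itertools.combinations(members, 2)
        if g.has_edge(u, v)
    )


def is_match(g: CompatibilityGraph, members: Sequence[int], tol: Tolerance) -> bool:
    """Validate the match definition for a set of graph vertex indices.

    True iff the pairing is one-to-one, every two members are adjacent in
    the compatibility graph, and all RPDs among them are pairwise
    compatible.
    """
    verts = [g.vertices[m] for m in members]
    if len({v.a_index for v in verts}) != len(verts):
        return False
    if len({v.b_index for v in verts}) != len(verts):
        return False
    rpds: list[float] = []
    for u, v in itertools.combinations(members, 2):
        r = g.rpd_edge(u, v)
        if r is None:
            return False
        rpds.append(r)
    return all(
        compatible(r1, r2, tol) for r1, r2 in itertools.combinations(rpds, 2)
    )


def legacy_mmm_match_test(
    members: Sequence[int], g: CompatibilityGraph, tol: Tolerance
) -> bool:
    """Triplet-based match criterion of the original algorithm.

    Tests every 3-subset of ``members`` in isolation: each triplet's three
    RPDs must exist and be mutually compatible.  RPD pairs that span
    disjoint vertex pairs are never checked — which is why this criterion
    is weaker than the full pairwise definition for sizes above 3.

    Raises
    ------
    ValueError
        If fewer than 3 members are given.
    """
    if len(members) < 3:
        raise ValueError("legacy match test requires at least 3 pairs")
    verts = [g.vertices[m] for m in members]
    if len({v.a_index for v in verts}) != len(verts) or len(
        {v.b_index for v in verts}
    ) != len(verts):
        raise ValueError("members must form a one-to-one pairing")
    for trip in itertools.combinations(members, 3):
        rpds = []
        for u, v in itertools.combinations(trip, 2):
            r = g.rpd_edge(u, v)
            if r is None:
                return False
            rpds.append(r)
        for r1, r2 in itertools.combinations(rpds, 2):
            if not compatible(r1, r2, tol):
                return False
    return True
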