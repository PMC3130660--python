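"""Brute-force reference solver and synthetic fixture generation.

The brute-force solver enumerates every admissible vertex subset directly
from the match definition, so the sweep solver can be tested against a
definitionally correct answer on small instances.  The generator builds
pairs of distance matrices from random additive trees where one matrix
contains a scaled (optionally noised) copy of a submatrix of the other —
a planted coevolving subset whose recovery is analytically predictable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .compat_core import (
    CompatibilityGraph,
    Tolerance,
    Vertex,
    build_compatibility_graph,
    compatible,
    delta_factor,
)
from .matrix_io import DistanceMatrix, write_phylip_square
from .mmm_solver import Match, SolverResult, _canonical_matches

__all__ = [
    "SynthSpec",
    "brute_force_solve",
    "random_tree_distances",
    "generate_pair",
    "write_fixture",
]

#: Hard cap on brute-force problem size (subset enumeration explodes).
BRUTE_FORCE_MAX_VERTICES = 20


def brute_force_solve(
    g: CompatibilityGraph, tol: Tolerance, max_vertices: int = BRUTE_FORCE_MAX_VERTICES
) -> SolverResult:
    """Enumerate all vertex subsets; keep the largest valid matches.

    A subset is valid when it is one-to-one, pairwise adjacent in the
    compatibility graph, and all its RPDs are pairwise compatible.  The
    enumeration extends partial subsets in index order and prunes as soon
    as a violation appears, which is safe because every subset of a match
    is a match.
    """
    n = g.n_vertices
    if n > max_vertices:
        raise ValueError(
            f"{n} vertices exceeds brute-force guard of {max_vertices}"
        )
    stats = {"vertices": n, "edges": g.n_edges, "method": "brute_force"}
    if n == 0:
        return SolverResult(0, [], stats)

    best = 0
    found: set[frozenset[int]] = set()
    rpd_of = g.rpd_edge

    def extend(start: int, members: list[int], rpds: list[float]) -> None:
        nonlocal best
        size = len(members)
        if size > best:
            best = size
            found.clear()
        if size == best and size > 0:
            found.add(frozenset(members))
        for v in range(start, n):
            if any(not g.has_edge(v, m) for m in members):
                continue
            new_rpds = [rpd_of(v, m) for m in members]
            if any(
                not compatible(r1, r2, tol)
                for r1 in new_rpds
                for r2 in rpds
            ):
                continue
            if any(
                not compatible(r1, r2, tol)
                for r1, r2 in itertools.combinations(new_rpds, 2)
            ):
                continue
            extend(v + 1, members + [v], rpds + new_rpds)

    extend(0, [], [])
    stats["score"] = best
    return SolverResult(best, _canonical_matches(g, found), stats)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic matrix pair with a planted match.

    ``noise`` is a multiplicative half-width: each planted B distance is
    ``scale * d_A * f`` with ``f`` drawn uniformly from
    ``[1 - noise, 1 + noise]``.  Because compatibility is a ratio
    criterion, the worst-case RPD spread is ``(1 + noise) / (1 - noise)``,
    which must not exceed ``delta(alpha)`` for the planted subset to be
    guaranteed to survive; the generator asserts this.
    """

    n_a: int
    n_b: int
    shared_species: int
    planted_size: int
    scale: float = 1.0
    noise: float = 0.0
    alpha: float = 0.1
    seed: int = 0
    mean_branch: float = 0.1

    def validate(self) -> None:
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("family sizes must be >= 1")
        if not 0 < self.shared_species <= min(self.n_a, self.n_b):
            raise ValueError("shared_species must be in [1, min(n_a, n_b)]")
        if not 0 <= self.planted_size <= self.shared_species:
            raise ValueError(
                "planted_size must not exceed shared_species "
                f"({self.planted_size} > {self.shared_species})"
            )
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not 0 <= self.noise < 1:
            raise ValueError("noise must be in [0, 1)")
        if self.noise > 0:
            spread = (1 + self.noise) / (1 - self.noise)
            if spread > delta_factor(self.alpha):
                raise ValueError(
                    f"noise spread {spread:.4f} exceeds tolerance slack "
                    f"delta({self.alpha}) = {delta_factor(self.alpha):.4f}; "
                    "the planted match would not be guaranteed to survive"
                )


def random_tree_distances(
    n: int, rng: np.random.Generator, mean_branch: float = 0.1
) -> np.ndarray:
    """Leaf-to-leaf distances of a random additive tree on ``n`` leaves.

    Topology by sequential random joins; branch lengths are
    Exponential(mean ``mean_branch``), typical of protein distances in
    substitutions/site.  Off-diagonal distances are positive (and distinct
    with probability 1).
    """
    dist = np.zeros((n, n))
    clusters: list[list[int]] = [[i] for i in range(n)]
    to_root = np.zeros(n)
    while len(clusters) > 1:
        i, j = rng.choice(len(clusters), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        e1, e2 = rng.exponential(mean_branch, size=2) + 1e-9
        left, right = clusters[i], clusters[j]
        to_root[left] += e1
        to_root[right] += e2
        for u in left:
            for v in right:
                dist[u, v] = dist[v, u] = to_root[u] + to_root[v]
        clusters[i] = left + right
        del clusters[j]
    return dist


def generate_pair(
    spec: SynthSpec,
) -> tuple[DistanceMatrix, DistanceMatrix, Match]:
    """Generate a matrix pair with a planted coevolving subset.

    Family A comes from one random tree.  The first ``planted_size`` B
    proteins copy the corresponding A submatrix scaled by ``spec.scale``
    and perturbed multiplicatively by ``spec.noise``; the rest of B comes
    from an independent random tree.  Species tags pair the first
    ``shared_species`` proteins of each family one-to-one; remaining
    proteins get private species so they can never be paired.

    Returns ``(mat_a, mat_b, planted)`` where ``planted`` is the planted
    match as A/B index pairs.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_a, n_b, p = spec.n_a, spec.n_b, spec.planted_size

    d_a = random_tree_distances(n_a, rng, spec.mean_branch)
    d_b = random_tree_distances(n_b, rng, spec.mean_branch)

    # plant: B[0:p, 0:p] := scale * A[0:p, 0:p] * noise factors
    for u in range(p):
        for v in range(u + 1, p):
            f = rng.uniform(1 - spec.noise, 1 + spec.noise) if spec.noise else 1.0
            val = spec.scale * d_a[u, v] * f
            d_b[u, v] = d_b[v, u] = val

    shared = spec.shared_species
    species_a = [f"s{t}" if t < shared else f"onlyA{t}" for t in range(n_a)]
    species_b = [f"s{t}" if t < shared else f"onlyB{t}" for t in range(n_b)]
    labels_a = [f"{species_a[t]}|a{t}" for t in range(n_a)]
    labels_b = [f"{species_b[t]}|b{t}" for t in range(n_b)]

    mat_a = DistanceMatrix(labels_a, d_a, species_a)
    mat_b = DistanceMatrix(labels_b, d_b, species_b)
    planted = Match(frozenset(Vertex(t, t) for t in range(p)))
    return mat_a, mat_b, planted


def write_fixture(
    spec: SynthSpec, outdir: Path, prefix: str = "pair"
) -> tuple[Path, Path, Path]:
    """Write a generated pair as PHYLIP files plus a JSON sidecar.

    The sidecar records the generating spec and the planted match so a
    fixture directory is self-describing.  Species tags are recoverable
    from the labels with delimiter ``|`` field 0.
    """
    mat_a, mat_b, planted = generate_pair(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path_a = outdir / f"{prefix}_A.phy"
    path_b = outdir / f"{prefix}_B.phy"
    path_meta = outdir / f"{prefix}_meta.json"
    write_phylip_square(mat_a, path_a)
    write_phylip_square(mat_b, path_b)
    meta = {
        "spec": asdict(spec),
        "planted": [
            [mat_a.labels[v.a_index], mat_b.labels[v.b_index]]
            for v in planted.sorted_pairs()
        ],
        "species_delimiter": "|",
        "species_field": 0,
    }
    path_meta.write_text(json.dumps(meta, indent=2) + "\n")
    return path_a, path_b, path_meta
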