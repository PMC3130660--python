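import itertools

import numpy as np
import pytest

from mmm2 import DistanceMatrix, Tolerance, build_compatibility_graph
from mmm2.oracle_synth import random_tree_distances


def make_dm(labels, values, species=None):
    return DistanceMatrix(list(labels), np.asarray(values, dtype=float), species)


def random_instance(rng, max_family=6, species=False):
    """A random compatibility graph from two independent tree matrices."""
    n_a = int(rng.integers(2, max_family + 1))
    n_b = int(rng.integers(2, max_family + 1))
    d_a = random_tree_distances(n_a, rng)
    d_b = random_tree_distances(n_b, rng)
    sp_a = sp_b = None
    if species:
        n_sp = int(rng.integers(1, 4))
        sp_a = [f"s{rng.integers(n_sp)}" for _ in range(n_a)]
        sp_b = [f"s{rng.integers(n_sp)}" for _ in range(n_b)]
    mat_a = make_dm([f"a{i}" for i in range(n_a)], d_a, sp_a)
    mat_b = make_dm([f"b{i}" for i in range(n_b)], d_b, sp_b)
    return build_compatibility_graph(mat_a, mat_b), mat_a, mat_b


def tie_heavy_instance(rng, max_family=5):
    """Matrices with small-integer distances so equal RPDs are common."""
    n_a = int(rng.integers(2, max_family + 1))
    n_b = int(rng.integers(2, max_family + 1))

    def integral(n):
        d = rng.integers(1, 4, (n, n)).astype(float)
        d = np.triu(d, 1)
        d = d + d.T
        return d

    mat_a = make_dm([f"a{i}" for i in range(n_a)], integral(n_a))
    mat_b = make_dm([f"b{i}" for i in range(n_b)], integral(n_b))
    return build_compatibility_graph(mat_a, mat_b), mat_a, mat_b


def exhaustive_max_cliques(n, edges):
    """Independent clique oracle: test all 2^n subsets for pairwise adjacency."""
    adjset = {u: set() for u in range(n)}
    for u, v in edges:
        adjset[u].add(v)
        adjset[v].add(u)
    best = 0
    cliques = []
    for mask in range(1 << n):
        members = [v for v in range(n) if (mask >> v) & 1]
        if len(members) < best:
            continue
        if all(v in adjset[u] for u, v in itertools.combinations(members, 2)):
            if len(members) > best:
                best = len(members)
                cliques = []
            cliques.append(frozenset(members))
    return best, sorted(cliques, key=sorted)


@pytest.fixture
def tol01():
    return Tolerance(0.1)


@pytest.fixture
def figure_instance():
    """Two 3-protein families whose A distances are exactly twice the B ones."""
    d_a = np.array([[0.0, 0.4, 0.6], [0.4, 0.0, 0.8], [0.6, 0.8, 0.0]])
    mat_a = make_dm(["a2", "a3", "a5"], d_a, ["s1", "s2", "s3"])
    mat_b = make_dm(["b3", "b7", "b8"], d_a / 2.0, ["s1", "s2", "s3"])
    return mat_a, mat_b


@pytest.fixture
def chain_witness():
    """Four pairings legal under the triplet criterion but not pairwise.

    RPDs: R(p0,p1) = 1.0 and R(p2,p3) = 1.15 never share a triplet, so the
    triplet test cannot see that their ratio exceeds delta(0.1) = 1.11...;
    all other RPDs sit at 1.07, compatible with both extremes.
    """
    d_a = np.full((4, 4), 1.07)
    d_a[0, 1] = d_a[1, 0] = 1.0
    d_a[2, 3] = d_a[3, 2] = 1.15
    np.fill_diagonal(d_a, 0.0)
    d_b = np.ones((4, 4))
    np.fill_diagonal(d_b, 0.0)
    sp = [f"s{i}" for i in range(4)]
    mat_a = make_dm([f"a{i}" for i in range(4)], d_a, sp)
    mat_b = make_dm([f"b{i}" for i in range(4)], d_b, sp)
    return build_compatibility_graph(mat_a, mat_b)
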