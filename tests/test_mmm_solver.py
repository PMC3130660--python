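import itertools

import numpy as np
import pytest

from mmm2 import (
    SimpleGraph,
    Tolerance,
    Vertex,
    brute_force_solve,
    build_compatibility_graph,
    is_match,
    legacy_mmm_match_test,
    match_edge_count,
    max_cliques_all,
    solve,
)
from mmm2.oracle_synth import SynthSpec, generate_pair, random_tree_distances

from .conftest import make_dm, random_instance, tie_heavy_instance


def solve_and_oracle(g, alpha):
    tol = Tolerance(alpha)
    got = solve(g, tol)
    exp = brute_force_solve(g, tol, max_vertices=40)
    return got, exp


class TestScaledCopy:
    def test_exact_scaled_copy_scores_family_size(self, tol01):
        rng = np.random.default_rng(5)
        d_a = random_tree_distances(5, rng)
        sp = [f"s{i}" for i in range(5)]
        mat_a = make_dm([f"a{i}" for i in range(5)], d_a, sp)
        mat_b = make_dm([f"b{i}" for i in range(5)], 2.0 * d_a, sp)
        g = build_compatibility_graph(mat_a, mat_b)
        res = solve(g, tol01)
        assert res.score == 5
        assert len(res.matches) == 1
        assert res.matches[0].pairs == frozenset(Vertex(i, i) for i in range(5))


class TestWorkedExample:
    def test_score_three_exact_pairing(self, figure_instance, tol01):
        mat_a, mat_b = figure_instance
        g = build_compatibility_graph(mat_a, mat_b)
        res = solve(g, tol01)
        assert res.score == 3
        assert len(res.matches) == 1
        assert res.matches[0].labels(g) == [
            ("a2", "b3"),
            ("a3", "b7"),
            ("a5", "b8"),
        ]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        g, _, _ = random_instance(rng, max_family=5, species=bool(seed % 2))
        for alpha in (0.0, 0.05, 0.1, 0.3):
            got, exp = solve_and_oracle(g, alpha)
            assert got.score == exp.score
            assert got.match_index_sets(g) == exp.match_index_sets(g)

    @pytest.mark.parametrize("seed", range(25))
    def test_tie_heavy_instances(self, seed):
        # small-integer distances produce many exactly equal RPDs, which is
        # what the index-based dedup rules must survive
        rng = np.random.default_rng(1000 + seed)
        g, _, _ = tie_heavy_instance(rng)
        for alpha in (0.0, 0.1, 0.3):
            got, exp = solve_and_oracle(g, alpha)
            assert got.score == exp.score
            assert got.match_index_sets(g) == exp.match_index_sets(g)


class TestDegenerateInputs:
    def test_empty_graph(self, tol01):
        mat_a = make_dm(["a1"], [[0.0]], ["s1"])
        mat_b = make_dm(["b1"], [[0.0]], ["s2"])
        g = build_compatibility_graph(mat_a, mat_b)
        res = solve(g, tol01)
        assert res.score == 0
        assert res.matches == []

    def test_vertices_but_no_edges_scores_one(self, tol01):
        mat_a = make_dm(["a1", "a2"], [[0.0, 0.0], [0.0, 0.0]], ["s1", "s2"])
        mat_b = make_dm(["b1", "b2"], [[0.0, 1.0], [1.0, 0.0]], ["s1", "s2"])
        g = build_compatibility_graph(mat_a, mat_b)
        res = solve(g, tol01)
        assert res.score == 1
        assert res.trivial
        assert {m.pairs for m in res.matches} == {
            frozenset({Vertex(0, 0)}),
            frozenset({Vertex(1, 1)}),
        }

    def test_single_edge_scores_two(self, tol01):
        mat_a = make_dm(["a1", "a2"], [[0.0, 1.0], [1.0, 0.0]], ["s1", "s2"])
        mat_b = make_dm(["b1", "b2"], [[0.0, 2.0], [2.0, 0.0]], ["s1", "s2"])
        g = build_compatibility_graph(mat_a, mat_b)
        res = solve(g, tol01)
        assert res.score == 2
        assert res.trivial
        assert len(res.matches) == 1

    def test_invalid_maxtrees(self, chain_witness, tol01):
        with pytest.raises(ValueError):
            solve(chain_witness, tol01, maxtrees="two")


class TestProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_scale_invariance(self, seed, tol01):
        rng = np.random.default_rng(300 + seed)
        g, mat_a, mat_b = random_instance(rng, max_family=4)
        base = solve(g, tol01)
        for c in (0.25, 3.0):
            scaled = make_dm(mat_b.labels, c * mat_b.values, mat_b.species)
            g2 = build_compatibility_graph(mat_a, scaled)
            res = solve(g2, tol01)
            assert res.score == base.score
            assert res.match_index_sets(g2) == base.match_index_sets(g)

    @pytest.mark.parametrize("seed", range(10))
    def test_swap_symmetry(self, seed, tol01):
        rng = np.random.default_rng(400 + seed)
        g, mat_a, mat_b = random_instance(rng, max_family=4)
        g_swapped = build_compatibility_graph(mat_b, mat_a)
        res = solve(g, tol01)
        res_swapped = solve(g_swapped, tol01)
        assert res.score == res_swapped.score
        mirrored = {
            frozenset(Vertex(v.b_index, v.a_index) for v in m.pairs)
            for m in res_swapped.matches
        }
        assert mirrored == {m.pairs for m in res.matches}

    @pytest.mark.parametrize("seed", range(10))
    def test_alpha_monotonicity(self, seed):
        rng = np.random.default_rng(500 + seed)
        g, _, _ = random_instance(rng, max_family=5)
        scores = [solve(g, Tolerance(a)).score for a in (0.0, 0.05, 0.1, 0.3, 0.7, 1.0)]
        assert scores == sorted(scores)

    @pytest.mark.parametrize("seed", range(5))
    def test_alpha_one_score_is_max_clique_of_graph(self, seed):
        rng = np.random.default_rng(600 + seed)
        g, _, _ = random_instance(rng, max_family=4)
        res = solve(g, Tolerance(1.0))
        sg = SimpleGraph(g.n_vertices, [g.adjacency_bits(u) for u in range(g.n_vertices)])
        size, _ = max_cliques_all(sg)
        assert res.score == max(size, 1 if g.n_vertices else 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_subset_closure(self, seed, tol01):
        rng = np.random.default_rng(700 + seed)
        g, _, _ = random_instance(rng, max_family=5)
        res = solve(g, tol01)
        pos = {v: idx for idx, v in enumerate(g.vertices)}
        for m in res.matches:
            members = [pos[p] for p in m.pairs]
            for size in range(2, len(members)):
                for sub in itertools.combinations(members, size):
                    assert is_match(g, sub, tol01)

    @pytest.mark.parametrize("seed", range(10))
    def test_maxtrees_one_contained_in_all(self, seed, tol01):
        rng = np.random.default_rng(800 + seed)
        g, _, _ = random_instance(rng, max_family=5)
        res_all = solve(g, tol01, maxtrees="all")
        res_one = solve(g, tol01, maxtrees="one")
        assert res_one.score == res_all.score
        assert len(res_one.matches) == 1
        assert res_one.match_index_sets(g) <= res_all.match_index_sets(g)

    def test_maxtrees_one_on_tied_maxima(self, tol01):
        # two disjoint species blocks yield two tied size-2 maxima at alpha=0
        d = [[0.0, 1.0, 0.0, 0.0], [1.0, 0.0, 0.0, 0.0],
             [0.0, 0.0, 0.0, 1.0], [0.0, 0.0, 1.0, 0.0]]
        sp = ["s1", "s2", "s3", "s4"]
        mat_a = make_dm(["a1", "a2", "a3", "a4"], d, sp)
        mat_b = make_dm(["b1", "b2", "b3", "b4"], d, sp)
        g = build_compatibility_graph(mat_a, mat_b)
        res_all = solve(g, Tolerance(0.0))
        res_one = solve(g, Tolerance(0.0), maxtrees=1)
        assert res_all.score == res_one.score == 2
        assert len(res_all.matches) == 2
        assert len(res_one.matches) == 1


class TestMatchValidation:
    def test_planted_size5_has_ten_edges(self, tol01):
        mat_a, mat_b, planted = generate_pair(
            SynthSpec(n_a=5, n_b=5, shared_species=5, planted_size=5, scale=2.0, seed=1)
        )
        g = build_compatibility_graph(mat_a, mat_b)
        res = solve(g, tol01)
        assert res.score == 5
        pos = {v: idx for idx, v in enumerate(g.vertices)}
        members = [pos[p] for p in res.matches[0].pairs]
        assert match_edge_count(g, members) == 10
        assert is_match(g, members, tol01)

    def test_non_one_to_one_rejected(self, tol01):
        mat_a = make_dm(["a1", "a2"], [[0.0, 1.0], [1.0, 0.0]])
        mat_b = make_dm(["b1", "b2"], [[0.0, 1.0], [1.0, 0.0]])
        g = build_compatibility_graph(mat_a, mat_b)
        pos = {v: idx for idx, v in enumerate(g.vertices)}
        # (a1,b1) and (a1,b2) share a row
        assert not is_match(g, [pos[Vertex(0, 0)], pos[Vertex(0, 1)]], tol01)


class TestLegacyComparator:
    def test_requires_at_least_three(self, chain_witness, tol01):
        with pytest.raises(ValueError):
            legacy_mmm_match_test([0, 1], chain_witness, tol01)

    def test_every_solver_match_passes_legacy(self, tol01):
        rng = np.random.default_rng(900)
        checked = 0
        for _ in range(60):
            g, _, _ = random_instance(rng, max_family=5)
            res = solve(g, tol01)
            if res.score < 3:
                continue
            pos = {v: idx for idx, v in enumerate(g.vertices)}
            for m in res.matches:
                assert legacy_mmm_match_test([pos[p] for p in m.pairs], g, tol01)
                checked += 1
        assert checked > 0

    def test_triplet_verdicts_identical(self, tol01):
        rng = np.random.default_rng(901)
        for _ in range(40):
            g, _, _ = random_instance(rng, max_family=4)
            pos_list = list(range(g.n_vertices))
            for trip in itertools.combinations(pos_list, 3):
                verts = [g.vertices[t] for t in trip]
                if len({v.a_index for v in verts}) < 3:
                    continue
                if len({v.b_index for v in verts}) < 3:
                    continue
                assert legacy_mmm_match_test(trip, g, tol01) == is_match(
                    g, trip, tol01
                )

    def test_chain_witness_separates_criteria(self, chain_witness, tol01):
        members = list(range(4))
        assert legacy_mmm_match_test(members, chain_witness, tol01)
        assert not is_match(chain_witness, members, tol01)
        assert solve(chain_witness, tol01).score == 3
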