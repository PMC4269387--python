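import itertools

import networkx as nx
import numpy as np
import pytest

import doubletsnet as dn
from doubletsnet import synth
from .conftest import random_connected_graph


def floyd_warshall_oracle(g):
    """Textbook O(n^3) all-pairs shortest paths, kept independent of the
    breadth-first implementation under test."""
    nodes = sorted(g)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in g.edges:
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return nodes, dist


def dfs_geodesics_oracle(g, s, t):
    """All shortest s-t paths by exhaustive depth-first enumeration."""
    best, found = [np.inf], []

    def rec(path):
        node = path[-1]
        if len(path) - 1 > best[0]:
            return
        if node == t:
            if len(path) - 1 < best[0]:
                best[0] = len(path) - 1
                found.clear()
            if len(path) - 1 == best[0]:
                found.append(tuple(path))
            return
        for nb in g[node]:
            if nb not in path:
                rec(path + [nb])

    rec([s])
    return sorted(found)


class TestAllPairsLengths:
    def test_love_hate_three_edges(self, love_hate_graph):
        mat = dn.all_pairs_lengths(love_hate_graph)
        assert mat.loc["LOVE", "HATE"] == 3  # two intermediate words
        assert (np.diag(mat.values) == 0).all()

    def test_unreachable_sentinel(self):
        lad = dn.build_ladder_graph(["AXE", "BOW"])
        mat = dn.all_pairs_lengths(lad)
        assert np.isinf(mat.loc["AXE", "BOW"])

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            g = nx.gnp_random_graph(
                int(rng.integers(2, 40)), 0.15, seed=int(rng.integers(2**31))
            )
            nodes, oracle = floyd_warshall_oracle(g)
            mat = dn.all_pairs_lengths(g).loc[nodes, nodes].to_numpy()
            assert np.array_equal(mat, oracle)

    def test_symmetry_and_triangle_inequality(self, component_graph):
        mat = dn.all_pairs_lengths(component_graph)
        vals = mat.to_numpy()
        assert np.array_equal(vals, vals.T)
        rng = np.random.default_rng(0)
        nodes = list(mat.index)
        for _ in range(200):
            a, b, c = rng.choice(len(nodes), size=3, replace=False)
            assert vals[a, c] <= vals[a, b] + vals[b, c]


class TestSolveDoublet:
    def test_dive_wipe_two_intermediates(self):
        lad = dn.build_ladder_graph(["DIVE", "DIRE", "WIRE", "WIPE"])
        sol = dn.solve_doublet(lad, "DIVE", "WIPE")
        assert sol.words == ("DIVE", "DIRE", "WIRE", "WIPE")
        assert sol.steps == 2

    def test_diver_wiper_six_intermediates(self):
        lad = dn.build_ladder_graph(
            ["DIVER", "RIVER", "RAVER", "CAVER", "CAPER", "PAPER", "PIPER", "WIPER"]
        )
        sol = dn.solve_doublet(lad, "DIVER", "WIPER")
        assert sol.steps == 6
        ok, why = dn.validate_ladder(sol.words)
        assert ok, why

    def test_same_word(self, love_hate_graph):
        sol = dn.solve_doublet(love_hate_graph, "LOVE", "LOVE")
        assert sol.words == ("LOVE",)
        assert sol.steps == 0

    def test_unreachable_pair_unsolvable(self):
        lad = dn.build_ladder_graph(["AXE", "BOW"])
        sol = dn.solve_doublet(lad, "AXE", "BOW")
        assert not sol.solvable
        assert sol.steps is None

    def test_absent_word_raises(self, love_hate_graph):
        with pytest.raises(KeyError):
            dn.solve_doublet(love_hate_graph, "LOVE", "MARE")

    def test_lexicographically_smallest_tie_break(self):
        # square: two geodesics AAA-(ABA|BAA)-BBA... build a 4-cycle of words
        lad = dn.build_ladder_graph(["AAA", "ABA", "BAA", "BBA"])
        sol = dn.solve_doublet(lad, "AAA", "BBA")
        assert sol.words == ("AAA", "ABA", "BBA")

    def test_steps_equal_edges_minus_one(self, component_graph):
        rng = np.random.default_rng(7)
        nodes = sorted(component_graph.nodes)
        for _ in range(20):
            a, b = rng.choice(len(nodes), size=2, replace=False)
            sol = dn.solve_doublet(component_graph, nodes[a], nodes[b])
            assert sol.steps == sol.n_edges - 1


class TestValidateLadder:
    def test_rogue_beast_printed_solution(self):
        ladder = synth.printed_ladders()["ROGUE-BEAST"]
        ok, why = dn.validate_ladder(ladder.words)
        assert ok, why
        assert ladder.steps == 10

    def test_rejects_multi_letter_jump(self):
        ok, why = dn.validate_ladder(["LOVE", "HATE"])
        assert not ok
        assert "one-letter" in why

    def test_accepts_short_chain(self):
        ok, _ = dn.validate_ladder(["CAT", "COT", "COG"])
        assert ok

    def test_rejects_repeats_and_length_mismatch(self):
        assert not dn.validate_ladder(["CAT", "COT", "CAT"])[0]
        assert not dn.validate_ladder(["CAT", "CART"])[0]
        assert not dn.validate_ladder(["CAT"])[0]


class TestEnumerateGeodesics:
    def test_four_cycle_two_geodesics(self):
        g = nx.Graph([("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")])
        gs = dn.enumerate_geodesics(g, "A", "D")
        assert len(gs) == 2
        assert gs.n_edges == 2

    def test_adjacent_pair_single_edge(self, love_hate_graph):
        gs = dn.enumerate_geodesics(love_hate_graph, "LOVE", "HOVE")
        assert gs.paths == (("LOVE", "HOVE"),)

    def test_unreachable_raises(self):
        lad = dn.build_ladder_graph(["AXE", "BOW"])
        with pytest.raises(ValueError):
            dn.enumerate_geodesics(lad, "AXE", "BOW")

    def test_matches_dfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            g = random_connected_graph(rng)
            nodes = sorted(g)
            for s, t in itertools.islice(itertools.combinations(nodes, 2), 12):
                if not nx.has_path(g, s, t):
                    continue
                gs = dn.enumerate_geodesics(g, s, t)
                assert sorted(gs.paths) == dfs_geodesics_oracle(g, s, t)

    def test_every_geodesic_is_a_valid_ladder(self, component_graph):
        gs = dn.enumerate_geodesics(component_graph, "DABBLING", "MINGLING")
        for p in gs.paths:
            ok, why = dn.validate_ladder(p)
            assert ok, why
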