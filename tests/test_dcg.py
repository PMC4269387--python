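import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import doubletsnet as dn
from doubletsnet import synth


def two_clique_transition(within=0.9, between=0.001, size=10):
    n = 2 * size
    w = np.full((n, n), between)
    w[:size, :size] = within
    w[size:, size:] = within
    np.fill_diagonal(w, 0.0)
    return pd.DataFrame(w / w.sum(1)[:, None])


class TestSimilarityAndTransition:
    def test_similarity_limits_and_monotonicity(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert dn.similarity_matrix(d, 1.0).iloc[0, 0] == 1.0
        s_small = dn.similarity_matrix(d, 0.01).iloc[0, 1]
        s_large = dn.similarity_matrix(d, 100.0).iloc[0, 1]
        assert s_small < 1e-10 and s_large > 0.99
        # closer pairs are more similar at any fixed T
        d2 = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        s = dn.similarity_matrix(d2, 1.5)
        assert s.iloc[0, 1] > s.iloc[0, 2]

    def test_nonpositive_temperature_raises(self):
        with pytest.raises(ValueError):
            dn.similarity_matrix(np.zeros((2, 2)), 0.0)

    def test_transition_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        sim = rng.uniform(0.01, 1.0, (10, 10))
        sim = (sim + sim.T) / 2
        trans = dn.transition_matrix(sim)
        assert np.allclose(trans.sum(1), 1.0, atol=1e-12)
        assert (trans.to_numpy() >= 0).all()
        assert np.all(np.diag(trans.to_numpy()) == 0)

    def test_two_node_transition(self):
        trans = dn.transition_matrix(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert np.allclose(trans.to_numpy(), [[0, 1], [1, 0]])

    def test_block_similarity_concentrates_mass(self):
        n = 10
        sim = np.full((2 * n, 2 * n), 0.01)
        sim[:n, :n] = 0.9
        sim[n:, n:] = 0.9
        trans = dn.transition_matrix(sim).to_numpy()
        within = trans[:n, :n].sum(1)
        assert (within > 0.95).all()

    def test_single_node_raises(self):
        with pytest.raises(ValueError):
            dn.transition_matrix(np.ones((1, 1)))


class TestRegulatedWalk:
    def test_bookkeeping(self):
        trans = two_clique_transition()
        rec = dn.regulated_walk(trans, rng=np.random.default_rng(0))
        assert len(rec.recurrence_times) == len(rec.removal_order)
        assert len(set(rec.removal_order)) == len(rec.removal_order)
        # every node partitioned, including the unremoved survivors
        assert set(rec.partition) == set(trans.index)

    def test_two_cliques_removed_in_blocks(self):
        # one clique's removals should complete before the other's begin,
        # with a spike marking the crossover
        trans = two_clique_transition()
        hits = 0
        rng = np.random.default_rng(1)
        for _ in range(100):
            rec = dn.regulated_walk(trans, rng=rng.spawn(1)[0])
            sides = [int(n >= 10) for n in rec.removal_order]
            if len(set(sides)) == 2 and sum(
                a != b for a, b in zip(sides, sides[1:])
            ) == 1 and rec.spike_positions:
                hits += 1
        assert hits >= 90

    def test_invalid_inputs(self):
        trans = two_clique_transition()
        with pytest.raises(ValueError):
            dn.regulated_walk(trans, visit_threshold=0)
        with pytest.raises(ValueError):
            dn.regulated_walk(np.ones((3, 3)))  # not row-stochastic


class TestEnsembleConnectivity:
    def test_two_clique_structure(self):
        trans = two_clique_transition()
        ens = dn.ensemble_connectivity(
            trans, n_walks=100, rng=np.random.default_rng(2)
        ).to_numpy()
        assert ens[:10, :10].min() >= 0.9
        assert ens[:10, 10:].max() <= 0.1

    def test_symmetric_unit_diagonal_bounds(self):
        trans = two_clique_transition()
        ens = dn.ensemble_connectivity(trans, n_walks=7,
                                       rng=np.random.default_rng(3)).to_numpy()
        assert np.allclose(ens, ens.T)
        assert np.all(np.diag(ens) == 1.0)
        assert ens.min() >= 0 and ens.max() <= 1

    def test_single_walk_is_binary(self):
        trans = two_clique_transition()
        ens = dn.ensemble_connectivity(trans, n_walks=1,
                                       rng=np.random.default_rng(4)).to_numpy()
        assert set(np.unique(ens)) <= {0.0, 1.0}

    def test_reproducible_given_seed(self):
        trans = two_clique_transition()
        a = dn.ensemble_connectivity(trans, 20, rng=np.random.default_rng(5))
        b = dn.ensemble_connectivity(trans, 20, rng=np.random.default_rng(5))
        assert a.equals(b)


class TestExtractCommunities:
    def test_exact_two_block(self):
        c = np.zeros((12, 12))
        c[:5, :5] = 1.0
        c[5:, 5:] = 1.0
        k, mem = dn.extract_communities(c)
        assert k == 2
        labs = [mem[i] for i in range(12)]
        assert adjusted_rand_score(labs, [0] * 5 + [1] * 7) == 1.0

    def test_noisy_three_block(self):
        rng = np.random.default_rng(6)
        truth = np.repeat([0, 1, 2], 8)
        c = np.where(truth[:, None] == truth[None, :], 0.95, 0.05)
        c += rng.normal(0, 0.01, c.shape)
        c = np.clip((c + c.T) / 2, 0, 1)
        np.fill_diagonal(c, 1.0)
        k, mem = dn.extract_communities(c)
        assert k == 3
        assert adjusted_rand_score([mem[i] for i in range(24)], truth) == 1.0

    def test_all_ones_single_community(self):
        k, mem = dn.extract_communities(np.ones((8, 8)))
        assert k == 1
        assert set(mem.values()) == {0}

    def test_cap_respected(self):
        c = np.eye(30) + 0.5 * np.eye(30)  # 30 strong singleton-ish modes
        k, _ = dn.extract_communities(c, max_k=6)
        assert k <= 6


class TestCommunityGeometry:
    def test_planted_two_block_lexicon(self):
        words, labels, _ = synth.generate_planted_lexicon()
        lad = dn.build_ladder_graph(words)
        res = dn.community_geometry(lad, n_scales=2, seed=0)
        first = res.partitions[0]
        nodes = sorted(first)
        ari = adjusted_rand_score(
            [labels[n] for n in nodes], [first[n] for n in nodes]
        )
        assert res.community_counts[0] == 2
        assert ari == 1.0

    def test_nesting_is_structural(self, component_graph):
        res = dn.community_geometry(component_graph, n_scales=4, seed=3)
        for fine, coarse in zip(res.communities, res.communities[1:]):
            for nodes in coarse.values():
                children = [c for c in fine.values() if c & nodes]
                assert frozenset().union(*children) == nodes
        assert res.community_counts == tuple(sorted(res.community_counts,
                                                    reverse=True))

    def test_deterministic_under_seed(self):
        words, _, _ = synth.generate_planted_lexicon()
        lad = dn.build_ladder_graph(words)
        a = dn.community_geometry(lad, n_scales=2, seed=11)
        b = dn.community_geometry(lad, n_scales=2, seed=11)
        assert a.scales == b.scales
        assert a.partitions == b.partitions
        assert a.merges == b.merges

    def test_merge_scales_annotated(self, component_graph):
        res = dn.community_geometry(component_graph, n_scales=4, seed=1)
        for children, parent, scale in res.merges:
            assert scale in res.scales
            assert len(children) >= 2

    def test_two_level_hierarchy_counts_and_nesting(self):
        g, labels = synth.generate_planted_hierarchy(seed=0)
        res = dn.community_geometry(g, n_scales=2, seed=0)
        assert res.community_counts == (4, 2)
        first, last = res.partitions[0], res.partitions[-1]
        nodes = sorted(first)
        assert adjusted_rand_score(
            [labels[n] for n in nodes], [first[n] for n in nodes]
        ) == 1.0
        assert adjusted_rand_score(
            [labels[n] // 2 for n in nodes], [last[n] for n in nodes]
        ) == 1.0

    def test_empty_scale_schedule_raises(self, component_graph):
        with pytest.raises(ValueError):
            dn.community_geometry(component_graph, scales=[])

    def test_serialization_roundtrip(self, component_graph):
        res = dn.community_geometry(component_graph, n_scales=2, seed=2)
        payload = res.to_dict()
        assert len(payload["levels"]) == 2
        total = sum(
            len(v) for v in payload["levels"][0]["communities"].values()
        )
        assert total == 52
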