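import networkx as nx
import pytest

import doubletsnet as dn
from doubletsnet import synth


@pytest.fixture(scope="session")
def component_words():
    return synth.eight_letter_component()


@pytest.fixture(scope="session")
def component_graph(component_words):
    return dn.build_ladder_graph(component_words)


@pytest.fixture(scope="session")
def component_stats(component_graph):
    return dn.edge_betweenness(component_graph)


@pytest.fixture(scope="session")
def component_kernel(component_stats):
    return dn.fit_kernel([s.betweenness for s in component_stats.values()])


@pytest.fixture(scope="session")
def component_distances(component_graph, component_stats, component_kernel):
    return dn.distance_table(component_graph, component_stats, component_kernel)


@pytest.fixture
def love_hate_graph():
    return dn.build_ladder_graph(["LOVE", "HOVE", "HAVE", "HATE"])


def random_connected_graph(rng, n_max=12):
    """Small random graph for oracle comparisons (not necessarily connected)."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.2, 0.7))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return g
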