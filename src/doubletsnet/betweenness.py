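"""Edge betweenness as a geodesic proportion, and functional edge typing.

The betweenness used here differs from the textbook (Girvan-Newman) edge
betweenness centrality: for a connected component with geodesic collection
P (all shortest paths between all unordered reachable pairs, counted with
tie multiplicity and including single-edge geodesics),

    B(e) = #{p in P : e in p} / |P|.

It shares rankings with the centrality variant on many graphs but not its
values; the conservation identity sum_e B(e) = mean edges per geodesic
pins the normalization down and is asserted in the tests.
"""

from __future__ import annotations

from collections import Counter, defaultdict, deque
from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd

from .lexicon import DEFAULT_VOWELS, LadderGraph, hamming_position


def _as_graph(g) -> nx.Graph:
    return g.graph if isinstance(g, LadderGraph) else g


def _edge_key(u, v):
    return (u, v) if u <= v else (v, u)


def geodesic_edge_counts(graph) -> tuple:
    """Raw geodesic counts: (per-edge counts, total geodesics).

    Exact integer arithmetic via a Brandes-style accumulation.  For each
    source s, a BFS records sigma(v) = number of shortest s-v paths and the
    shortest-path DAG; a reverse sweep computes g(v) = number of DAG paths
    starting at v (to any descendant, the empty path included), so the
    number of s-geodesics through DAG edge (u, v) is sigma(u) * g(v).
    Unordered pairs are counted once (every directed count appears twice).
    """
    g = _as_graph(graph)
    counts: Counter = Counter()
    total = 0
    for s in g:
        dist = {s: 0}
        sigma = {s: 1}
        preds = defaultdict(list)
        order = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in g[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        npaths = {v: 1 for v in order}  # DAG paths out of v, incl. length 0
        for v in reversed(order):
            for u in preds[v]:
                counts[_edge_key(u, v)] += sigma[u] * npaths[v]
                npaths[u] += npaths[v]
        total += sum(sigma[t] for t in order) - 1
    assert total % 2 == 0
    return {e: c // 2 for e, c in counts.items()}, total // 2


@dataclass(frozen=True)
class EdgeStats:
    """Per-edge betweenness proportion plus functional type labels."""

    edge: tuple
    betweenness: float
    #: exact value, for oracle comparisons
    betweenness_exact: Fraction
    #: CC / VV / VC from the first letters of the two endpoint words
    node_type: str | None
    #: cc / vv / vc from the two letters exchanged at the differing slot
    change_type: str | None
    #: 1-based index of the differing slot
    changed_position: int | None


def classify_edge(edge, vowel_set: frozenset = DEFAULT_VOWELS) -> tuple:
    """(node_type, change_type, 1-based changed position) of a word edge."""
    a, b = edge
    pos = hamming_position(a, b)
    if pos is None:
        raise ValueError(f"{a!r}-{b!r} is not a one-letter substitution")

    def _nt(x, y):
        kinds = sorted("V" if c in vowel_set else "C" for c in (x, y))
        return "".join(reversed(kinds))  # mixed pairs normalize to VC / vc

    node_type = _nt(a[0], b[0])
    change_type = _nt(a[pos], b[pos]).lower()
    return node_type, change_type, pos + 1


def edge_betweenness(graph, vowel_set: frozenset = DEFAULT_VOWELS) -> dict:
    """Betweenness proportion (and type labels for word graphs) per edge.

    Computed per connected component: the geodesic collection of a
    component is normalized by that component's own total.  Word-type
    labels are attached when nodes are strings; for generic binary graphs
    the label fields are None.
    """
    g = _as_graph(graph)
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    stats: dict = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        counts, total = geodesic_edge_counts(sub)
        for e in sub.edges:
            key = _edge_key(*e)
            frac = Fraction(counts.get(key, 0), total)
            labelled = all(isinstance(w, str) for w in key)
            nt, ct, pos = (
                classify_edge(key, vowel_set) if labelled else (None, None, None)
            )
            stats[key] = EdgeStats(
                edge=key,
                betweenness=float(frac),
                betweenness_exact=frac,
                node_type=nt,
                change_type=ct,
                changed_position=pos,
            )
    return stats


def betweenness_values(stats: dict) -> dict:
    """Plain edge -> float betweenness map from an EdgeStats map."""
    return {e: s.betweenness for e, s in stats.items()}


NODE_TYPES = ("VC", "VV", "CC")
CHANGE_TYPES = ("vc", "vv", "cc")


@dataclass
class EnrichmentTable:
    """Observed vs random-baseline counts of functional edge types among
    the top-fraction high-betweenness edges."""

    observed: pd.DataFrame  # node_type x change_type counts
    baseline: pd.DataFrame  # mean counts over seeded random edge draws
    top_fraction: float
    #: number of edges in the top set after threshold-tie expansion
    n_top: int
    n_replicates: int
    seed: int

    def formatted(self) -> pd.DataFrame:
        """'observed(baseline)' cells, baseline to 3 decimals."""
        out = self.observed.astype(str).copy()
        for r in out.index:
            for c in out.columns:
                out.loc[r, c] = (
                    f"{self.observed.loc[r, c]}({self.baseline.loc[r, c]:.3f})"
                )
        return out


def _type_counts(edges, vowel_set) -> pd.DataFrame:
    table = pd.DataFrame(0, index=list(NODE_TYPES), columns=list(CHANGE_TYPES))
    for e in edges:
        nt, ct, _ = classify_edge(e, vowel_set)
        table.loc[nt, ct] += 1
    return table


def enrichment_table(
    graph,
    top_fraction: float = 0.05,
    seed: int = 0,
    n_replicates: int = 100,
    vowel_set: frozenset = DEFAULT_VOWELS,
    stats: dict | None = None,
) -> EnrichmentTable:
    """Functional-type enrichment of the highest-betweenness edges.

    The top set is the ceil(top_fraction * |E|) highest-betweenness edges,
    expanded to include every edge tied with the threshold value.  The
    baseline is the mean type table over ``n_replicates`` seeded uniform
    draws (without replacement) of equally many edges.
    """
    g = _as_graph(graph)
    if stats is None:
        stats = edge_betweenness(g, vowel_set)
    edges = sorted(stats, key=lambda e: (-stats[e].betweenness_exact, e))
    m = int(np.ceil(top_fraction * len(edges)))
    if m < 1 or m > len(edges):
        raise ValueError("top fraction selects no edges or more than exist")
    threshold = stats[edges[m - 1]].betweenness_exact
    top = [e for e in edges if stats[e].betweenness_exact >= threshold]
    observed = _type_counts(top, vowel_set)

    rng = np.random.default_rng(seed)
    acc = np.zeros((len(NODE_TYPES), len(CHANGE_TYPES)))
    for _ in range(n_replicates):
        draw = rng.choice(len(edges), size=len(top), replace=False)
        acc += _type_counts([edges[i] for i in draw], vowel_set).to_numpy()
    baseline = pd.DataFrame(
        acc / n_replicates, index=list(NODE_TYPES), columns=list(CHANGE_TYPES)
    )
    return EnrichmentTable(
        observed=observed,
        baseline=baseline,
        top_fraction=top_fraction,
        n_top=len(top),
        n_replicates=n_replicates,
        seed=seed,
    )
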