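"""Shortest paths, Doublets puzzle solving and the step-count convention.

A ladder's *steps* count the intermediate words, i.e. edges - 1: the
printed two-step solution LOVE-HOVE-HAVE-HATE uses three edges.  All
functions here report both conventions where relevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .lexicon import LadderGraph, hamming_position


def _as_graph(g) -> nx.Graph:
    return g.graph if isinstance(g, LadderGraph) else g


def all_pairs_lengths(ladder) -> pd.DataFrame:
    """Symmetric matrix of shortest-path lengths in edges.

    Unreachable pairs get ``inf``.  Per-source breadth-first search is the
    workhorse; a Floyd-Warshall run gives identical output and is kept as a
    cross-check in the test suite.
    """
    g = _as_graph(ladder)
    nodes = sorted(g)
    mat = pd.DataFrame(np.inf, index=nodes, columns=nodes)
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for dst, d in dists.items():
            mat.loc[src, dst] = d
    return mat


@dataclass(frozen=True)
class LadderSolution:
    """A solved (or unsolvable) Doublets puzzle."""

    source: str
    target: str
    #: full word sequence source..target, or None when no ladder exists
    words: tuple | None

    @property
    def solvable(self) -> bool:
        return self.words is not None

    @property
    def steps(self) -> int | None:
        """Number of intermediate words (edges - 1)."""
        return None if self.words is None else max(len(self.words) - 2, 0)

    @property
    def n_edges(self) -> int | None:
        return None if self.words is None else len(self.words) - 1


def solve_doublet(ladder, source: str, target: str) -> LadderSolution:
    """Shortest ladder between two words, lexicographically smallest on ties.

    Greedy walk down a distance field from the target: at each node pick the
    alphabetically first neighbor that is one step closer, which yields the
    lexicographically smallest geodesic.
    """
    g = _as_graph(ladder)
    for w in (source, target):
        if w not in g:
            raise KeyError(f"{w!r} not in graph")
    if source == target:
        return LadderSolution(source, target, (source,))
    dist = nx.single_source_shortest_path_length(g, target)
    if source not in dist:
        return LadderSolution(source, target, None)
    path = [source]
    cur = source
    while cur != target:
        cur = min(nb for nb in g[cur] if dist.get(nb, np.inf) == dist[cur] - 1)
        path.append(cur)
    return LadderSolution(source, target, tuple(path))


def validate_ladder(words) -> tuple:
    """Check a word sequence for ladder validity.

    Returns ``(ok, violation)`` where ``violation`` is a human-readable
    description of the first problem, or None.
    """
    words = [w.upper() for w in words]
    if len(words) < 2:
        return False, "a ladder needs at least 2 words"
    if len(set(words)) != len(words):
        return False, "repeated word"
    length = len(words[0])
    for w in words[1:]:
        if len(w) != length:
            return False, f"{w} has length {len(w)}, expected {length}"
    for a, b in zip(words, words[1:]):
        if hamming_position(a, b) is None:
            return False, f"{a} -> {b} is not a one-letter change"
    return True, None


@dataclass(frozen=True)
class GeodesicSet:
    """All shortest paths between one node pair."""

    source: str
    target: str
    paths: tuple  # tuple of word tuples, each of minimal equal length

    @property
    def n_edges(self) -> int:
        return len(self.paths[0]) - 1

    def __len__(self) -> int:
        return len(self.paths)


def enumerate_geodesics(ladder, source, target) -> GeodesicSet:
    """Every shortest path between a reachable pair, sorted for stability."""
    g = _as_graph(ladder)
    try:
        paths = sorted(tuple(p) for p in nx.all_shortest_paths(g, source, target))
    except nx.NetworkXNoPath:
        raise ValueError(f"{source!r} and {target!r} are not connected")
    return GeodesicSet(source, target, tuple(paths))
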