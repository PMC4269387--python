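"""Packaged fixtures and seeded generators.

Two kinds of inputs exercise the whole pipeline without any external
dictionary:

* printed fixtures: the 52-word second-largest component of the 8-letter
  stratum (with its published node numbering) and four solved ladders;
* generators: planted-community ladder lexicons (dense word families
  joined by sparse one-edge bridges) and generic planted-partition binary
  graphs, both returning ground-truth labels for recovery tests.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np

from .paths import LadderSolution

#: printed node numbering of the 52-word component (1-based, printed order)
COMPONENT_NODE_NUMBERING = {}


def eight_letter_component() -> list:
    """The 52 eight-letter words of the second-largest component fixture.

    Returned uppercased in printed order; ``COMPONENT_NODE_NUMBERING`` carries the
    published 1-based node numbering (gangling=17, gargling=19, ...).
    """
    text = (
        resources.files("doubletsnet.data").joinpath("eight_letter_component.txt").read_text("utf-8")
    )
    words = [
        line.strip().upper()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if not COMPONENT_NODE_NUMBERING:
        COMPONENT_NODE_NUMBERING.update({w: i + 1 for i, w in enumerate(words)})
    return words


def printed_ladders() -> dict:
    """Four published solved ladders, keyed by 'SOURCE-TARGET'."""
    raw = {
        "LOVE-HATE": ("LOVE", "HOVE", "HAVE", "HATE"),
        "ROGUE-BEAST": (
            "ROGUE", "VOGUE", "VAGUE", "VALUE", "VALVE", "HALVE",
            "HELVE", "HEAVE", "LEAVE", "LEASE", "LEAST", "BEAST",
        ),
        "DIVE-WIPE": ("DIVE", "DIRE", "WIRE", "WIPE"),
        "DIVER-WIPER": (
            "DIVER", "RIVER", "RAVER", "CAVER",
            "CAPER", "PAPER", "PIPER", "WIPER",
        ),
    }
    return {
        key: LadderSolution(words[0], words[-1], words)
        for key, words in raw.items()
    }


@dataclass(frozen=True)
class PlantedLexiconSpec:
    """Planted word families: each family fills a rook's-grid of two free
    slots over a family-specific letter pool, consecutive families are
    joined by exactly ``bridges_per_join`` one-letter bridges."""

    n_families: int = 2
    family_size: int = 12
    length: int = 8
    bridges_per_join: int = 1
    seed: int = 0


def generate_planted_lexicon(spec: PlantedLexiconSpec = PlantedLexiconSpec()):
    """Seeded ladder lexicon with planted families and sparse bridges.

    Family words share ``length - 3`` fixed letters; they differ at a
    family-marker position (position 0) and two free slots.  Free slot 1
    draws from a family-private consonant pool and free slot 2 from a pool
    shared by all families, so within-family words form a dense rook's
    graph while cross-family pairs differ in at least two positions --
    except the designated bridge words, which reuse one free-slot tuple
    across two consecutive families and so create exactly one
    inter-family edge per bridge.

    Returns ``(words, labels, bridges)``: the word list, a word -> family
    map, and the list of planted inter-family edges.
    """
    if spec.length < 4:
        raise ValueError("length must be at least 4 (marker + 2 free slots)")
    rng = np.random.default_rng(spec.seed)
    letters = string.ascii_uppercase
    markers = letters[: spec.n_families]  # family marker at position 0
    shared_pool = "AEIOU"  # free slot 2, shared across families
    private_size = 4
    pools = [
        letters[5 + f * private_size: 5 + (f + 1) * private_size]
        for f in range(spec.n_families)
    ]
    if 5 + spec.n_families * private_size > 26:
        raise ValueError("too many families for disjoint letter pools")
    capacity = private_size * len(shared_pool)
    if spec.family_size > capacity:
        raise ValueError(
            f"family_size {spec.family_size} exceeds template capacity {capacity}"
        )

    # common skeleton for the fixed positions 3..length-1
    skeleton = "".join(rng.choice(list("BCDFG"), size=spec.length - 3))

    def make_word(f, a, b):
        return markers[f] + a + b + skeleton

    words, labels = [], {}
    family_tuples = []
    for f in range(spec.n_families):
        tuples = [
            (a, b) for a in pools[f] for b in shared_pool
        ][: spec.family_size]
        family_tuples.append(tuples)
        for a, b in tuples:
            w = make_word(f, a, b)
            words.append(w)
            labels[w] = f

    bridges = []
    bridge_letters = iter("ZYXWV")  # outside every family pool
    for f in range(spec.n_families - 1):
        for j in range(spec.bridges_per_join):
            x = next(bridge_letters)
            shared_b = shared_pool[j % len(shared_pool)]
            wa = make_word(f, x, shared_b)
            wb = make_word(f + 1, x, shared_b)
            for w, fam in ((wa, f), (wb, f + 1)):
                words.append(w)
                labels[w] = fam
            bridges.append((min(wa, wb), max(wa, wb)))
    return words, labels, bridges


@dataclass(frozen=True)
class PlantedGraphSpec:
    """Planted-partition (stochastic block model) binary graph."""

    block_sizes: tuple = (15, 15, 15)
    p_in: float = 0.8
    p_out: float = 0.02
    seed: int = 0


def generate_planted_graph(spec: PlantedGraphSpec = PlantedGraphSpec()):
    """Seeded Bernoulli block graph and its ground-truth labels.

    Returns ``(graph, labels)`` with integer nodes 0..n-1 and a node ->
    block map.  ``p_in``/``p_out`` may also be a full block probability
    matrix passed as ``p_in`` (then ``p_out`` is ignored), enabling
    two-level planted hierarchies.
    """
    sizes = list(spec.block_sizes)
    b = len(sizes)
    if np.ndim(spec.p_in) == 2:
        p = np.asarray(spec.p_in, dtype=float)
    else:
        for prob in (spec.p_in, spec.p_out):
            if not 0 <= prob <= 1:
                raise ValueError("edge probabilities must be in [0, 1]")
        p = np.full((b, b), spec.p_out)
        np.fill_diagonal(p, spec.p_in)
    g = nx.stochastic_block_model(sizes, p.tolist(), seed=int(spec.seed))
    labels = {n: g.nodes[n]["block"] for n in g}
    plain = nx.Graph()
    plain.add_nodes_from(g.nodes)
    plain.add_edges_from(g.edges)
    return plain, labels


def generate_planted_hierarchy(
    block_size: int = 12,
    p_in: float = 0.85,
    sibling_bridges: int = 2,
    cross_bridges: int = 1,
    seed: int = 0,
):
    """Two-level planted hierarchy of four dense blocks.

    Blocks 0+1 and 2+3 form superblocks.  Within-block edges are Bernoulli
    (``p_in``, resampled until the block is connected); levels are joined
    by *fixed numbers* of bridge edges -- ``sibling_bridges`` between the
    blocks of a superblock and ``cross_bridges`` between the superblocks.
    Sparse explicit bridges (rather than a Bernoulli rate) mirror the
    dense-family/sparse-bridge regime of ladder lexicons and give bridge
    edges the high betweenness the kernel distance keys on.

    Returns ``(graph, labels)``; fine labels 0..3, superblock = label // 2.
    """
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    nodes = {
        b: list(range(b * block_size, (b + 1) * block_size)) for b in range(4)
    }
    labels = {}
    for b, ns in nodes.items():
        g.add_nodes_from(ns)
        for n in ns:
            labels[n] = b
        while True:
            edges = [
                (u, v)
                for i, u in enumerate(ns)
                for v in ns[i + 1:]
                if rng.random() < p_in
            ]
            h = nx.Graph()
            h.add_nodes_from(ns)
            h.add_edges_from(edges)
            if nx.is_connected(h):
                break
        g.add_edges_from(edges)

    def bridge(a, b, k):
        added = set()
        while len(added) < k:
            e = (int(rng.choice(nodes[a])), int(rng.choice(nodes[b])))
            if e not in added:
                g.add_edge(*e)
                added.add(e)

    bridge(0, 1, sibling_bridges)
    bridge(2, 3, sibling_bridges)
    bridge(1, 2, cross_bridges)
    return g, labels


def intra_inter_density(graph, labels) -> tuple:
    """(intra, inter) edge densities given ground-truth labels."""
    g = graph.graph if hasattr(graph, "graph") and isinstance(
        getattr(graph, "graph"), nx.Graph
    ) else graph
    nodes = list(g)
    intra_e = inter_e = 0
    for u, v in g.edges:
        if labels[u] == labels[v]:
            intra_e += 1
        else:
            inter_e += 1
    from collections import Counter

    sizes = Counter(labels[n] for n in nodes)
    intra_pairs = sum(s * (s - 1) // 2 for s in sizes.values())
    total_pairs = len(nodes) * (len(nodes) - 1) // 2
    inter_pairs = total_pairs - intra_pairs
    return (
        intra_e / intra_pairs if intra_pairs else 0.0,
        inter_e / inter_pairs if inter_pairs else 0.0,
    )
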