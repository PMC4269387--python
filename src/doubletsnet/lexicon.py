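"""Lexicons, ladder graphs and node/stratum statistics.

A *lexicon* is a normalized set of uppercase words partitioned into strata
by letter length.  A *ladder graph* is the graph of one stratum: nodes are
the words, and two words are joined iff they differ at exactly one letter
position (Hamming distance 1).  Node statistics follow the word-game
conventions: a word's *capacity* is the maximum conceivable degree
(|alphabet| - 1) x length, and a word is a *V-word* or *C-word* according
to whether its first letter is a vowel letter.
"""

from __future__ import annotations

import string
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

DEFAULT_ALPHABET = frozenset(string.ascii_uppercase)
DEFAULT_VOWELS = frozenset("AEIOU")
#: vowel letters including orthographic Y, for callers who opt in
VOWELS_WITH_Y = frozenset("AEIOUY")


@dataclass(frozen=True)
class Lexicon:
    """Normalized word set with alphabet, vowel set and per-length strata."""

    words: frozenset
    alphabet: frozenset = DEFAULT_ALPHABET
    vowel_set: frozenset = DEFAULT_VOWELS
    #: words skipped during normalization (non-alphabet characters)
    skipped: tuple = ()

    @property
    def strata(self) -> Mapping[int, frozenset]:
        by_len = defaultdict(set)
        for w in self.words:
            by_len[len(w)].add(w)
        return {n: frozenset(ws) for n, ws in sorted(by_len.items())}

    def stratum(self, length: int) -> frozenset:
        return frozenset(w for w in self.words if len(w) == length)

    def __len__(self) -> int:
        return len(self.words)


def _normalize(raw: Iterable[str], alphabet: frozenset) -> tuple:
    kept, skipped = set(), []
    for line in raw:
        token = line.strip().upper()
        if not token or token.startswith("#"):
            continue
        if all(c in alphabet for c in token):
            kept.add(token)
        else:
            skipped.append(token)
    return kept, skipped


def lexicon_from_words(
    words: Iterable[str],
    alphabet: frozenset = DEFAULT_ALPHABET,
    vowel_set: frozenset = DEFAULT_VOWELS,
) -> Lexicon:
    """Build a lexicon from an in-memory word iterable.

    Words are uppercased and deduplicated; tokens containing characters
    outside ``alphabet`` (hyphens, apostrophes, diacritics, ...) are skipped
    and recorded on ``Lexicon.skipped``.
    """
    kept, skipped = _normalize(words, frozenset(alphabet))
    if not kept:
        raise ValueError("empty lexicon after normalization")
    return Lexicon(frozenset(kept), frozenset(alphabet), frozenset(vowel_set),
                   tuple(skipped))


def load_word_list(
    path,
    alphabet: frozenset = DEFAULT_ALPHABET,
    vowel_set: frozenset = DEFAULT_VOWELS,
) -> Lexicon:
    """Read a word list: UTF-8 text, one word per line, ``#`` comments."""
    text = Path(path).read_text(encoding="utf-8")
    return lexicon_from_words(text.splitlines(), alphabet, vowel_set)


@dataclass
class LadderGraph:
    """One stratum's graph: equal-length words joined by 1-letter changes."""

    length: int
    graph: nx.Graph

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    @property
    def component_labels(self) -> dict:
        labels = {}
        for cid, comp in enumerate(
            sorted(nx.connected_components(self.graph), key=lambda c: (-len(c), min(c)))
        ):
            for w in comp:
                labels[w] = cid
        return labels

    def number_of_components(self) -> int:
        return nx.number_connected_components(self.graph)


def hamming_position(a: str, b: str):
    """0-based index of the single differing position, or None."""
    if len(a) != len(b):
        return None
    pos = -1
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            if pos >= 0:
                return None
            pos = i
    return pos if pos >= 0 else None


def build_ladder_graph(source, length: int | None = None) -> LadderGraph:
    """Build the ladder graph of one stratum.

    ``source`` is a :class:`Lexicon` or any iterable of equal-length words.
    Edges are found with the wildcard-bucket method: two words are adjacent
    iff they share a pattern with exactly one position masked out, so the
    scan is linear in total word length rather than quadratic in words.
    """
    if isinstance(source, Lexicon):
        if length is None:
            occupied = sorted(source.strata)
            if len(occupied) != 1:
                raise ValueError("length required for a multi-stratum lexicon")
            length = occupied[0]
        words = sorted(source.stratum(length))
    else:
        words = sorted({w.strip().upper() for w in source})
        if length is None:
            length = len(words[0]) if words else 0
        words = [w for w in words if len(w) == length]
    if not words:
        raise ValueError(f"no words of length {length}")

    g = nx.Graph()
    g.add_nodes_from(words)
    buckets = defaultdict(list)
    for w in words:
        for i in range(length):
            buckets[w[:i] + "\0" + w[i + 1:]].append(w)
    for group in buckets.values():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                g.add_edge(group[i], group[j])
    return LadderGraph(length=length, graph=g)


@dataclass(frozen=True)
class NodeProfile:
    word: str
    degree: int
    #: per-position neighbor counts; sums to ``degree``
    slot_counts: tuple
    #: (|alphabet| - 1) x length, the conceivable maximum degree
    capacity: int
    #: 'V' if the first letter is a vowel letter, else 'C'
    word_type: str


def word_type(word: str, vowel_set: frozenset = DEFAULT_VOWELS) -> str:
    return "V" if word[0] in vowel_set else "C"


def node_profile(
    ladder: LadderGraph,
    word: str,
    vowel_set: frozenset = DEFAULT_VOWELS,
    alphabet_size: int = 26,
) -> NodeProfile:
    """Degree decomposition of one word over its letter slots."""
    g = ladder.graph if isinstance(ladder, LadderGraph) else ladder
    if word not in g:
        raise KeyError(f"{word!r} not in graph")
    slots = [0] * len(word)
    for nb in g[word]:
        slots[hamming_position(word, nb)] += 1
    return NodeProfile(
        word=word,
        degree=g.degree(word),
        slot_counts=tuple(slots),
        capacity=(alphabet_size - 1) * len(word),
        word_type=word_type(word, vowel_set),
    )


def degree_by_type_table(
    ladder: LadderGraph, vowel_set: frozenset = DEFAULT_VOWELS
) -> pd.DataFrame:
    """Contingency table of word type (rows C-word, V-word) vs degree."""
    g = ladder.graph if isinstance(ladder, LadderGraph) else ladder
    if g.number_of_nodes() == 0:
        return pd.DataFrame(index=["C-word", "V-word"])
    max_deg = max(d for _, d in g.degree)
    table = pd.DataFrame(
        0, index=["C-word", "V-word"], columns=range(max_deg + 1)
    )
    for w, d in g.degree:
        table.loc[f"{word_type(w, vowel_set)}-word", d] += 1
    return table


def stratum_summary(lexicon: Lexicon) -> pd.DataFrame:
    """Per-length word count, largest-component size and its proportion.

    The proportion of words in the largest connected component is the
    system-level heterogeneity index: near 1 the stratum is one giant
    component, near 0 it is scattered singletons.
    """
    rows = []
    for length, words in lexicon.strata.items():
        ladder = build_ladder_graph(sorted(words), length)
        comps = list(nx.connected_components(ladder.graph))
        largest = max(len(c) for c in comps)
        rows.append(
            {
                "length": length,
                "word_count": len(words),
                "largest_component": largest,
                "proportion": largest / len(words),
                "n_isolated": sum(1 for c in comps if len(c) == 1),
            }
        )
    return pd.DataFrame(rows).set_index("length")
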