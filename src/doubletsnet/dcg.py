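"""Multiscale community geometry via data cloud geometry (DCG).

Given a node-to-node distance table and a temperature scale T, nodes are
re-weighted by the similarity s_T(i,j) = exp(-d(i,j)/T): pairs much closer
than T look almost identical (s near 1), pairs much farther apart become
invisible (s near 0).  On the weighted complete graph a row-stochastic
transition matrix L(T) = D^-1 W drives a *regulated* random walk that
removes each node once its visit count exceeds a threshold.  Because the
walk lingers inside tightly-coupled groups, removals come in bursts: a
spike in the removal recurrence-time profile marks entry into a fresh
community, so the runs between spikes partition the nodes.  Averaging
co-membership over many walks gives an ensemble connectivity matrix whose
leading eigenvalues reveal the number of communities; complete-linkage
clustering of (1 - ensemble) recovers their membership.  Sweeping T over
an increasing schedule and recording how fine-scale cores merge into
conglomerates yields the community geometry: a hierarchy of partitions in
which the scale at which two communities merge acts as the distance
between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .betweenness import edge_betweenness
from .kerneldist import ScaleSchedule, distance_table, fit_kernel, select_scales
from .lexicon import LadderGraph


def similarity_matrix(dist_table, T: float) -> pd.DataFrame:
    """Temperature-indexed similarity s_T = exp(-d/T), unit diagonal."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if isinstance(dist_table, pd.DataFrame):
        d = dist_table.to_numpy(dtype=float)
        labels = list(dist_table.index)
    else:
        d = np.asarray(dist_table, dtype=float)
        labels = list(range(d.shape[0]))
    s = np.exp(-d / T)
    np.fill_diagonal(s, 1.0)
    return pd.DataFrame(s, index=labels, columns=labels)


def transition_matrix(similarity) -> pd.DataFrame:
    """Row-stochastic Markov matrix L = D^-1 W with zero self-weight."""
    if isinstance(similarity, pd.DataFrame):
        w = similarity.to_numpy(dtype=float).copy()
        labels = list(similarity.index)
    else:
        w = np.asarray(similarity, dtype=float).copy()
        labels = list(range(w.shape[0]))
    if w.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    np.fill_diagonal(w, 0.0)
    rowsums = w.sum(axis=1)
    if np.any(rowsums <= 0):
        raise ValueError("similarity row with no positive off-diagonal mass")
    return pd.DataFrame(w / rowsums[:, None], index=labels, columns=labels)


@dataclass(frozen=True)
class WalkRecord:
    """One regulated random walk: removals, recurrence profile, partition."""

    removal_order: tuple
    #: steps between consecutive removals (first entry: steps from start)
    recurrence_times: tuple
    #: indices into removal_order where a new community is entered
    spike_positions: tuple
    #: node -> community id; unremoved survivors attach to the block they
    #: are most strongly coupled to
    partition: dict


def _detect_spikes(recurrence: np.ndarray, n_sd: float) -> list:
    """Indices whose recurrence time exceeds mean + n_sd * SD.

    The first entry is excluded both as a candidate and from the baseline:
    it counts the warm-up steps before any node reaches the removal
    threshold, which is an order of magnitude larger than in-community
    recurrence and would otherwise mask genuine spikes.
    """
    if recurrence.size < 3:
        return []
    base = recurrence[1:]
    mu, sd = base.mean(), base.std()
    if sd == 0:
        return []
    return [
        int(i)
        for i in np.nonzero(recurrence > mu + n_sd * sd)[0]
        if i > 0
    ]


def regulated_walk(
    transition,
    visit_threshold: int = 5,
    rng=None,
    spike_sd: float = 2.0,
    restart_on_removal: bool = False,
) -> WalkRecord:
    """Run one regulated random walk and segment its removal record.

    The walk starts at a uniformly random node and at each step samples the
    current node's transition row restricted (and renormalized) to the
    surviving nodes.  A node is removed once its visit count exceeds
    ``visit_threshold``; after a removal the walk continues from the
    removed node's row by default, or teleports to a random survivor when
    ``restart_on_removal`` is set.  The walk stops when at most 2 nodes
    survive; each survivor joins the block receiving the most of its
    transition mass.
    """
    if visit_threshold < 1:
        raise ValueError("visit_threshold must be >= 1")
    rng = np.random.default_rng(rng)
    if isinstance(transition, pd.DataFrame):
        P = transition.to_numpy(dtype=float)
        labels = list(transition.index)
    else:
        P = np.asarray(transition, dtype=float)
        labels = list(range(P.shape[0]))
    n = P.shape[0]
    if n == 0 or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix must be row-stochastic")

    alive = np.ones(n, dtype=bool)
    visits = np.zeros(n, dtype=int)
    removal_order: list = []
    recurrence: list = []
    steps_since_removal = 0
    current = int(rng.integers(n))

    while alive.sum() > 2:
        visits[current] += 1
        steps_since_removal += 1
        if visits[current] > visit_threshold:
            alive[current] = False
            removal_order.append(current)
            recurrence.append(steps_since_removal)
            steps_since_removal = 0
            if restart_on_removal:
                nxt_pool = np.nonzero(alive)[0]
                current = int(rng.choice(nxt_pool))
                continue
        row = P[current] * alive
        total = row.sum()
        if total <= 0:  # defensive; cannot occur with exponential similarity
            row = alive.astype(float)
            total = row.sum()
        current = int(rng.choice(n, p=row / total))

    rec = np.asarray(recurrence, dtype=float)
    spikes = _detect_spikes(rec, spike_sd)
    partition: dict = {}
    block_of: dict = {}
    block = 0
    for i, node in enumerate(removal_order):
        if i in spikes:
            block += 1
        partition[labels[node]] = block
        block_of[node] = block
    # the <=2 survivors were never removed: attach each to the block it is
    # most strongly coupled to under the transition kernel
    for node in np.nonzero(alive)[0]:
        if block_of:
            mass = np.zeros(block + 1)
            for other, b in block_of.items():
                mass[b] += P[node, other]
            partition[labels[node]] = int(np.argmax(mass))
        else:
            partition[labels[node]] = 0
    return WalkRecord(
        removal_order=tuple(labels[i] for i in removal_order),
        recurrence_times=tuple(recurrence),
        spike_positions=tuple(spikes),
        partition=partition,
    )


def ensemble_connectivity(
    transition,
    n_walks: int = 100,
    visit_threshold: int = 5,
    rng=None,
    spike_sd: float = 2.0,
    restart_on_removal: bool = False,
) -> pd.DataFrame:
    """Co-membership probability matrix over many regulated walks."""
    if n_walks < 1:
        raise ValueError("n_walks must be >= 1")
    rng = np.random.default_rng(rng)
    if isinstance(transition, pd.DataFrame):
        labels = list(transition.index)
    else:
        labels = list(range(np.asarray(transition).shape[0]))
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    acc = np.zeros((n, n))
    # one independent child stream per walk: n_walks can grow without
    # reshuffling earlier walks
    for child in rng.spawn(n_walks):
        rec = regulated_walk(
            transition,
            visit_threshold=visit_threshold,
            rng=child,
            spike_sd=spike_sd,
            restart_on_removal=restart_on_removal,
        )
        members = np.empty(n, dtype=int)
        for lab, b in rec.partition.items():
            members[index[lab]] = b
        acc += members[:, None] == members[None, :]
    acc /= n_walks
    np.fill_diagonal(acc, 1.0)
    return pd.DataFrame(acc, index=labels, columns=labels)


def extract_communities(ensemble, max_k: int = 12, eps: float = 1e-9) -> tuple:
    """(k, membership) from an ensemble connectivity matrix.

    k counts the leading eigenvalues of the ensemble matrix exceeding the
    singleton baseline of 1 (a lone node contributes exactly its unit
    diagonal, a coherent community of size m contributes an eigenvalue
    near m times its mean co-membership), capped at ``max_k``; membership
    comes from complete-linkage hierarchical clustering of 1 - ensemble
    cut into k groups.
    """
    if isinstance(ensemble, pd.DataFrame):
        C = ensemble.to_numpy(dtype=float)
        labels = list(ensemble.index)
    else:
        C = np.asarray(ensemble, dtype=float)
        labels = list(range(C.shape[0]))
    n = C.shape[0]
    if n == 1:
        return 1, {labels[0]: 0}
    eig = np.sort(np.linalg.eigvalsh((C + C.T) / 2))[::-1]
    eig = np.clip(eig, eps, None)
    k = int(min(max(np.sum(eig > 1.0), 1), max_k, n))

    if k == 1:
        return 1, {lab: 0 for lab in labels}
    dist = 1.0 - C
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return k, {lab: int(c) - 1 for lab, c in zip(labels, flat)}


@dataclass
class GeometryResult:
    """Multiscale community hierarchy (the community geometry).

    ``partitions[l]`` maps node -> community id at ``scales[l]``; the ids
    are global across levels.  ``merges`` lists (child ids, parent id,
    scale) events; nesting is guaranteed: every community at one scale is
    a union of communities at the previous scale.
    """

    scales: tuple
    scale_provenance: tuple
    partitions: list
    #: per level: community id -> frozenset of nodes
    communities: list
    #: (tuple of child community ids, parent community id, scale)
    merges: list
    seed: object = None

    @property
    def community_counts(self) -> tuple:
        return tuple(len(c) for c in self.communities)

    def membership_frame(self) -> pd.DataFrame:
        nodes = sorted(self.partitions[0])
        return pd.DataFrame(
            {f"T={s:g}": [p[n] for n in nodes]
             for s, p in zip(self.scales, self.partitions)},
            index=nodes,
        )

    def to_dict(self) -> dict:
        return {
            "scales": list(self.scales),
            "scale_provenance": list(self.scale_provenance),
            "levels": [
                {
                    "scale": s,
                    "k": len(comms),
                    "communities": {
                        str(cid): sorted(map(str, nodes))
                        for cid, nodes in comms.items()
                    },
                }
                for s, comms in zip(self.scales, self.communities)
            ],
            "merges": [
                {"children": list(ch), "parent": p, "scale": s}
                for ch, p, s in self.merges
            ],
        }


def _nest_partition(fine: dict, raw_coarse: dict) -> dict:
    """Map each fine community to the raw coarse community holding the
    majority of its nodes; returns node -> nested coarse label."""
    groups: dict = {}
    for node, c in fine.items():
        groups.setdefault(c, []).append(node)
    mapping = {}
    for c, nodes in groups.items():
        votes: dict = {}
        for node in nodes:
            votes[raw_coarse[node]] = votes.get(raw_coarse[node], 0) + 1
        mapping[c] = max(sorted(votes), key=lambda t: votes[t])
    return {node: mapping[c] for node, c in fine.items()}


def community_geometry(
    graph,
    scales=None,
    n_scales: int = 4,
    n_walks: int = 100,
    visit_threshold: int = 5,
    spike_sd: float = 2.0,
    mode: str = "mean",
    seed=None,
    restart_on_removal: bool = False,
    dist=None,
) -> GeometryResult:
    """Full pipeline: betweenness -> kernel -> distances -> scales -> DCG.

    ``graph`` is a LadderGraph or any undirected networkx graph.  When
    ``scales`` is None a schedule of ``n_scales`` temperatures is selected
    from the pairwise-distance distribution.  Connected components are
    processed independently (distances across components are undefined)
    and their partitions concatenated.  The result's partitions are nested
    by construction: each coarser community is a union of finer ones,
    obtained by majority-overlap mapping of fine communities into the raw
    coarse partition.
    """
    g = graph.graph if isinstance(graph, LadderGraph) else graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(seed)

    if dist is None:
        stats = edge_betweenness(g)
        kernel = fit_kernel([s.betweenness for s in stats.values()])
        dist = distance_table(g, stats, kernel, mode=mode)
    if scales is None:
        schedule = select_scales(dist, n_scales=n_scales)
    elif isinstance(scales, ScaleSchedule):
        schedule = scales
    else:
        schedule = ScaleSchedule(tuple(scales), ("given",) * len(tuple(scales)))
    if len(schedule) == 0:
        raise ValueError("empty scale schedule")

    # raw per-scale partitions, components handled independently
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    raw_partitions = []
    for T in schedule.scales:
        part: dict = {}
        offset = 0
        for members in comps:
            if len(members) == 1:
                part[members[0]] = offset
                offset += 1
                continue
            sub = dist.loc[members, members]
            sim = similarity_matrix(sub, T)
            trans = transition_matrix(sim)
            ens = ensemble_connectivity(
                trans,
                n_walks=n_walks,
                visit_threshold=visit_threshold,
                rng=rng.spawn(1)[0],
                spike_sd=spike_sd,
                restart_on_removal=restart_on_removal,
            )
            k, membership = extract_communities(ens)
            for node, c in membership.items():
                part[node] = offset + c
            offset += k
        raw_partitions.append(part)

    # enforce nesting and assign global community ids
    nested = [raw_partitions[0]]
    for raw in raw_partitions[1:]:
        nested.append(_nest_partition(nested[-1], raw))

    partitions = []
    communities = []
    merges = []
    next_id = 0
    prev_comm_id: dict = {}  # fine local label -> global id
    for level, part in enumerate(nested):
        groups: dict = {}
        for node, c in part.items():
            groups.setdefault(c, set()).add(node)
        local_to_global = {}
        level_comms = {}
        for c in sorted(groups, key=lambda c: min(map(str, groups[c]))):
            nodes = frozenset(groups[c])
            if level > 0:
                children = sorted(
                    {prev_comm_id[nested[level - 1][n]] for n in nodes}
                )
                if len(children) == 1:
                    gid = children[0]  # unchanged community persists
                else:
                    gid = next_id
                    next_id += 1
                    merges.append(
                        (tuple(children), gid, schedule.scales[level])
                    )
            else:
                gid = next_id
                next_id += 1
            local_to_global[c] = gid
            level_comms[gid] = nodes
        partitions.append({n: local_to_global[c] for n, c in part.items()})
        prev_comm_id = {c: local_to_global[c] for c in local_to_global}
        communities.append(level_comms)

    return GeometryResult(
        scales=schedule.scales,
        scale_provenance=schedule.provenance,
        partitions=partitions,
        communities=communities,
        merges=merges,
        seed=seed,
    )
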