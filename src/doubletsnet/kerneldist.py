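"""Betweenness kernel and node-to-node distances.

The distance construction has three steps:

1. Pool the betweenness values of all directly connected pairs and fit an
   exponential a*exp(-b*x) to the tail of their histogram (log-linear least
   squares over the bins to the right of the modal bin, which holds the
   near-vertical mass of low-betweenness edges).
2. The kernel kappa(x) = 1 / (a*exp(-b*x)) = exp(b*x)/a maps betweenness to
   an edge cost: near-zero betweenness is compressed toward zero cost,
   large betweenness is stretched exponentially.
3. The distance between two nodes aggregates per-geodesic costs
   sum_{e in path} kappa(B(e)) over the geodesic collection between them
   (mean by default, minimum as an option); directly connected pairs
   reduce to kappa(B(edge)).

Candidate temperature scales for the community-geometry stage are read off
the tail of the pairwise-distance distribution: each bump beyond the main
mode aggregates cross-community pair distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import signal, stats as sps

from .betweenness import EdgeStats
from .lexicon import LadderGraph


def _as_graph(g) -> nx.Graph:
    return g.graph if isinstance(g, LadderGraph) else g


def _as_float_map(edge_stats: dict) -> dict:
    return {
        e: (s.betweenness if isinstance(s, EdgeStats) else float(s))
        for e, s in edge_stats.items()
    }


@dataclass(frozen=True)
class KernelParams:
    """Fitted reciprocal-exponential kernel kappa(x) = exp(b*x)/a."""

    amplitude: float  # a > 0
    rate: float  # b > 0
    bin_edges: tuple
    residuals: tuple

    def tail(self, x):
        """The fitted exponential tail f(x) = a*exp(-b*x)."""
        return self.amplitude * np.exp(-self.rate * np.asarray(x, float))

    def __call__(self, x):
        return 1.0 / self.tail(x)


def fit_kernel(betweenness_values, bins="fd") -> KernelParams:
    """Fit the exponential betweenness-histogram tail and return its kernel.

    Uses Freedman-Diaconis binning by default; the fit domain is every bin
    strictly to the right of the modal bin, excluding empty bins (log of
    zero).  Raises for degenerate inputs where no tail exists.
    """
    x = np.asarray(
        [v.betweenness if isinstance(v, EdgeStats) else float(v)
         for v in betweenness_values],
        dtype=float,
    )
    if x.size < 10:
        raise ValueError("need at least 10 betweenness values to fit a kernel")
    if np.ptp(x) == 0:
        raise ValueError(
            "all betweenness values identical; no tail to fit - supply a "
            "manual kernel (any increasing positive function) instead"
        )
    counts, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    modal = int(np.argmax(counts))
    tail = np.arange(modal + 1, len(counts))
    tail = tail[counts[tail] > 0]
    if tail.size < 2:
        # too few occupied tail bins at this resolution; refine binning
        counts, edges = np.histogram(x, bins=max(10, 2 * len(counts)))
        centers = 0.5 * (edges[:-1] + edges[1:])
        modal = int(np.argmax(counts))
        tail = np.arange(modal + 1, len(counts))
        tail = tail[counts[tail] > 0]
    if tail.size < 2:
        raise ValueError("betweenness histogram has no usable tail")
    # count-weighted log-linear fit (Poisson-motivated: var(log c) ~ 1/c),
    # so sparsely occupied far-tail bins cannot flatten the slope
    slope, intercept = np.polyfit(
        centers[tail], np.log(counts[tail]), 1, w=np.sqrt(counts[tail])
    )
    if slope >= 0:
        raise ValueError("histogram tail is not decreasing; cannot fit kernel")
    fitted = intercept + slope * centers[tail]
    return KernelParams(
        amplitude=float(np.exp(intercept)),
        rate=float(-slope),
        bin_edges=tuple(edges),
        residuals=tuple(np.log(counts[tail]) - fitted),
    )


def distance_table(
    graph,
    edge_stats: dict,
    kernel,
    mode: str = "mean",
) -> pd.DataFrame:
    """Symmetric node-to-node distance table.

    For each reachable pair the cost of one geodesic is the sum of
    kappa(B(e)) over its edges; the pair's distance aggregates these costs
    over the full geodesic collection with ``mode`` 'mean' (default) or
    'min'.  Cross-component pairs are NaN; the diagonal is 0.
    """
    if mode not in ("mean", "min"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    g = _as_graph(graph)
    bmap = _as_float_map(edge_stats)
    cost = {e: float(kernel(b)) for e, b in bmap.items()}

    def edge_cost(u, v):
        return cost[(u, v) if u <= v else (v, u)]

    nodes = sorted(g)
    table = pd.DataFrame(np.nan, index=nodes, columns=nodes, dtype=float)
    np.fill_diagonal(table.values, 0.0)
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        members = sorted(comp)
        for i, s in enumerate(members):
            # one BFS-DAG per source; aggregate geodesic costs target-wise
            agg = _source_geodesic_costs(sub, s, edge_cost, mode)
            for t, d in agg.items():
                table.loc[s, t] = d
                table.loc[t, s] = d
    return table


def _source_geodesic_costs(g, s, edge_cost, mode) -> dict:
    """Aggregate geodesic costs from s to every reachable t in one sweep.

    Dynamic programming over the shortest-path DAG: with A(t) the mean
    (or min) cost of all geodesics s->t and sigma(t) their count, the
    recurrence runs over DAG predecessors p of t:
      mean: A(t) = sum_p sigma(p)*(A(p) + c(p,t)) / sigma(t)
      min : A(t) = min_p (A(p) + c(p,t)).
    """
    from collections import deque

    dist = {s: 0}
    sigma = {s: 1}
    agg = {s: 0.0}
    order = []
    queue = deque([s])
    preds = {s: []}
    while queue:
        v = queue.popleft()
        order.append(v)
        for w in g[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                preds[w] = []
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    for t in order[1:]:
        costs_in = [
            (sigma[p], agg[p] + edge_cost(p, t)) for p in preds[t]
        ]
        if mode == "min":
            agg[t] = min(c for _, c in costs_in)
        else:
            agg[t] = sum(w * c for w, c in costs_in) / sigma[t]
    del agg[s]
    return agg


@dataclass(frozen=True)
class ScaleSchedule:
    """Strictly increasing temperature scales with their provenance."""

    scales: tuple
    #: per scale: 'bump' (anchored on distance-density bumps) or 'quantile'
    provenance: tuple
    #: detected local maxima of the distance density (baseline bump first)
    bumps: tuple = ()

    def __iter__(self):
        return iter(self.scales)

    def __len__(self):
        return len(self.scales)


_FALLBACK_QUANTILES = (0.80, 0.90, 0.95, 0.99)


def distance_bumps(
    d: np.ndarray,
    bandwidth: str | float = 0.1,
    prominence_frac: float = 0.01,
    grid_size: int = 800,
) -> list:
    """Local maxima of the pairwise-distance density, in log-distance space.

    Multiscale separations differ by ratios (similarity depends on d/T), so
    the kernel-density estimate runs on log10 distances; the default
    bandwidth factor 0.1 resolves bumps less than an order of magnitude
    apart, which a Silverman-type rule smears out on strongly multimodal
    inputs.  The first bump is the baseline: the within-community distance
    aggregation.  Bumps further out along the tail each collect the
    separations of one level of community structure.
    """
    d = np.asarray(d, dtype=float)
    d = d[np.isfinite(d) & (d > 0)]
    kde = sps.gaussian_kde(np.log10(d), bw_method=bandwidth)
    grid = np.linspace(
        np.log10(d.min()) - 0.2, np.log10(d.max()) + 0.2, grid_size
    )
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, prominence=prominence_frac * dens.max())
    return [float(10 ** grid[p]) for p in peaks]


def select_scales(
    dist_table,
    n_scales: int = 4,
    bandwidth: str | float = 0.1,
    prominence_frac: float = 0.01,
    grid_size: int = 800,
) -> ScaleSchedule:
    """Temperature schedule from bumps in the pairwise-distance distribution.

    The informative temperature range is anchored on the detected bumps:
    the finest useful scale is the baseline (within-community) bump itself
    -- below it partitions fragment into noise -- and the coarsest useful
    scale is the last tail bump divided by e^2, at which the pairs of the
    largest separation still have similarity exp(-e^2) ~ 0 (the top-level
    split survives) while every lesser separation has melted.  ``n_scales``
    temperatures are geometrically spaced across that range.  When fewer
    than two bumps are detected the schedule falls back to upper quantiles
    of the distance distribution (0.80/0.90/0.95/0.99), flagged in
    ``provenance``.
    """
    if isinstance(dist_table, pd.DataFrame):
        vals = dist_table.to_numpy(dtype=float)
    else:
        vals = np.asarray(dist_table, dtype=float)
    iu = np.triu_indices(vals.shape[0], k=1)
    d = vals[iu]
    d = d[np.isfinite(d)]
    if np.unique(d).size < 2:
        raise ValueError("need at least 2 distinct pairwise distances")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")

    bumps = distance_bumps(d, bandwidth, prominence_frac, grid_size)
    if len(bumps) >= 2:
        t_lo = bumps[0]
        t_hi = bumps[-1] / float(np.e ** 2)
        if t_hi <= t_lo:
            t_hi = t_lo * float(np.e)
        scales = np.geomspace(t_lo, t_hi, n_scales) if n_scales > 1 else [t_lo]
        return ScaleSchedule(
            scales=tuple(float(s) for s in scales),
            provenance=("bump",) * n_scales,
            bumps=tuple(bumps),
        )
    # degenerate density: fall back to upper quantiles
    qs = [float(np.quantile(d, q)) for q in _FALLBACK_QUANTILES[:n_scales]]
    scales = sorted(set(qs))
    if len(scales) < min(n_scales, 2):
        raise ValueError("could not assemble a scale schedule")
    return ScaleSchedule(
        scales=tuple(scales),
        provenance=("quantile",) * len(scales),
        bumps=tuple(bumps),
    )
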