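"""Spearman correlation networks with fragmentation-based cutoff selection.

The inference recipe:

1. Compute the marker x marker Spearman rho matrix for one group.
2. Scan a descending grid of candidate cutoffs and keep the highest cutoff
   at which the graph ``{|rho| >= tau}`` — restricted to markers that retain
   at least one edge — forms a single connected component ("the highest
   level of correlation for which the network is not fragmented").
3. Build the network at that cutoff and summarize its topology: node/edge
   counts, median degree, average clustering coefficient, and hubs (nodes
   whose degree strictly exceeds the 80th percentile of the degree
   distribution).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from scipy import stats

from .datatypes import (
    CorrelationMatrix,
    MarkerMatrix,
    MarkerNetwork,
    NetworkSummary,
    ParameterError,
)

__all__ = [
    "spearman_matrix",
    "default_grid",
    "select_threshold",
    "build_network",
    "detect_hubs",
    "summarize_network",
]


def spearman_matrix(mat: MarkerMatrix, markers: list[str] | None = None) -> CorrelationMatrix:
    """Spearman rho matrix: Pearson correlation of average-ranked columns.

    Ties get average ranks. A constant marker has no defined rank
    correlation against anything; its rho entries are set to 0 and the
    marker is recorded in ``constant_markers`` rather than propagating NaN.
    """
    cols = mat.marker_ids if markers is None else list(markers)
    x = mat.values_for(cols)
    n = x.shape[0]
    if n < 3:
        raise ParameterError(f"need >= 3 samples for rank correlation, got {n}")
    ranks = stats.rankdata(x, axis=0)
    sd = ranks.std(axis=0)
    constant = [cols[j] for j in np.flatnonzero(sd == 0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant cols -> NaN
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(rho)
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(cols, rho, n, constant)


def default_grid(start: float = 0.95, stop: float = 0.05, step: float = 0.05) -> np.ndarray:
    """Descending cutoff grid, default 0.95, 0.90, ..., 0.05."""
    n = int(round((start - stop) / step)) + 1
    return np.round(np.linspace(start, stop, n), 10)


def _component_count(rho: np.ndarray, tau: float, strict: bool) -> int:
    """Connected components of {|rho| >= tau}; strict counts isolated markers."""
    adj = np.abs(rho) >= tau
    np.fill_diagonal(adj, False)
    keep = adj.any(axis=0)
    if strict:
        if not keep.all():
            return int((~keep).sum()) + _count_components(adj[np.ix_(keep, keep)])
        return _count_components(adj)
    if not keep.any():
        return 0
    return _count_components(adj[np.ix_(keep, keep)])


def _count_components(adj: np.ndarray) -> int:
    if adj.shape[0] == 0:
        return 0
    g = nx.from_numpy_array(adj.astype(int))
    return nx.number_connected_components(g)


def select_threshold(
    corr: CorrelationMatrix,
    grid: np.ndarray | list[float] | None = None,
    strict: bool = False,
) -> float:
    """Highest grid cutoff at which the retained network is unfragmented.

    By default fragmentation is judged among non-isolated markers (markers
    with no surviving edge are dropped first, mirroring published node
    counts below the full panel size). With ``strict=True`` every marker
    must belong to the single component. If no grid value qualifies, the
    smallest one is returned with a fragmentation warning.
    """
    grid = default_grid() if grid is None else np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ParameterError("empty cutoff grid")
    if np.any(grid <= 0) or np.any(grid > 1):
        raise ParameterError("grid values must lie in (0, 1]")
    if not np.all(np.diff(grid) < 0):
        raise ParameterError("grid must be strictly descending")
    for tau in grid:
        if _component_count(corr.rho, tau, strict) == 1:
            return float(tau)
    warnings.warn(
        f"network fragmented at every cutoff down to {grid[-1]:g}; returning it",
        stacklevel=2,
    )
    return float(grid[-1])


def build_network(corr: CorrelationMatrix, tau: float, group: str = "") -> MarkerNetwork:
    """Graph with edges ``|rho| >= tau`` (signed rho as weight); isolated
    markers are excluded."""
    if not 0 < tau <= 1:
        raise ParameterError(f"tau must be in (0, 1], got {tau}")
    g = nx.Graph()
    rho = corr.rho
    ids = corr.marker_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(rho[i, j]) >= tau:
                g.add_edge(ids[i], ids[j], weight=float(rho[i, j]))
    return MarkerNetwork(g, float(tau), group)


def detect_hubs(net: MarkerNetwork, percentile: float = 80.0) -> list[tuple[str, int]]:
    """Nodes whose degree strictly exceeds the given percentile of the
    degree distribution (linear-interpolation percentile), sorted by degree
    descending, ties alphabetical."""
    if net.n_nodes == 0:
        raise ParameterError("empty network has no hubs")
    if not 0 < percentile < 100:
        raise ParameterError("percentile must be in (0, 100)")
    degrees = net.degrees()
    cut = float(np.percentile(list(degrees.values()), percentile))
    hubs = [(m, d) for m, d in degrees.items() if d > cut]
    return sorted(hubs, key=lambda md: (-md[1], md[0]))


def summarize_network(net: MarkerNetwork, hub_percentile: float = 80.0) -> NetworkSummary:
    """Topology summary: node/edge counts, median degree (midpoint
    convention), average clustering coefficient (nodes of degree < 2
    contribute 0), and the hub list."""
    if net.n_nodes == 0:
        return NetworkSummary(net.group, 0, 0, 0.0, 0.0, [], {})
    degrees = net.degrees()
    return NetworkSummary(
        group=net.group,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        median_degree=float(np.median(list(degrees.values()))),
        avg_clustering=float(nx.average_clustering(net.graph)),
        hubs=detect_hubs(net, hub_percentile),
        degrees=degrees,
    )
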