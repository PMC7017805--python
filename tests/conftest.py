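"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the code paths they check: Spearman via
explicit average ranks and the textbook Pearson formula, connectivity via
union-find, clustering via triangle enumeration, percentiles via the
sort-and-interpolate definition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kynet.datatypes import MarkerMatrix


def make_matrix(
    values,
    markers=None,
    group="G",
    units=None,
    groups=None,
    patients=None,
    marker_class=None,
) -> MarkerMatrix:
    """Build a MarkerMatrix from a plain array (default unit NPX)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    markers = markers or [f"M{j + 1}" for j in range(p)]
    samples = [f"S{i + 1}" for i in range(n)]
    data = pd.DataFrame(values, index=samples, columns=markers)
    grp = pd.Series(groups if groups is not None else [group] * n, index=samples)
    units = units or {m: "NPX" for m in markers}
    pats = pd.Series(patients, index=samples) if patients is not None else None
    return MarkerMatrix(data, grp, units, pats, marker_class or {})


# ---------------------------------------------------------------- oracles


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks of a 1-D array, computed by explicit tie grouping."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def pearson_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    denom = np.sqrt((dx ** 2).sum() * (dy ** 2).sum())
    return float((dx * dy).sum() / denom) if denom > 0 else np.nan


def brute_spearman(x: np.ndarray, y: np.ndarray) -> float:
    return pearson_formula(average_ranks(x), average_ranks(y))


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def brute_threshold(rho: np.ndarray, grid, strict: bool = False):
    """Exhaustive scan: for each cutoff, union-find connectivity of
    {|rho| >= tau}; return the first (largest) unfragmented cutoff, else
    the smallest grid value."""
    p = rho.shape[0]
    for tau in grid:
        uf = UnionFind(p)
        has_edge = [False] * p
        for i in range(p):
            for j in range(i + 1, p):
                if abs(rho[i, j]) >= tau:
                    uf.union(i, j)
                    has_edge[i] = has_edge[j] = True
        nodes = range(p) if strict else [i for i in range(p) if has_edge[i]]
        roots = {uf.find(i) for i in nodes}
        if len(roots) == 1:
            return float(tau)
    return float(grid[-1])


def brute_clustering(adj: dict[str, set[str]]) -> float:
    """Average local clustering by direct triangle enumeration; nodes with
    degree < 2 contribute 0."""
    total = 0.0
    for node, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            continue
        nbrs = list(nbrs)
        links = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if nbrs[b] in adj[nbrs[a]]
        )
        total += 2.0 * links / (k * (k - 1))
    return total / len(adj) if adj else 0.0


def brute_percentile(values, q: float) -> float:
    """Linear-interpolation percentile computed from the sorted sample."""
    v = sorted(float(x) for x in values)
    pos = (len(v) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
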