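"""Differential network topology: pre- vs during-treatment comparison.

Three comparisons mirror the published analysis:

* a permutation test on the edge-count difference between the two group
  networks at a fixed correlation cutoff (sample group labels are
  reshuffled, both networks rebuilt per permutation);
* a two-sample Kolmogorov-Smirnov test on the two degree distributions;
* overlap bookkeeping between each network's hub set and a list of
  differentially expressed markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .datatypes import MarkerMatrix, NetworkSummary, ParameterError

__all__ = [
    "PermutationResult",
    "permutation_edge_test",
    "ks_degree_test",
    "HubOverlap",
    "hub_overlap",
]


def _edge_count(values: np.ndarray, tau: float) -> int:
    """Edges of the Spearman network {|rho| >= tau}; constant columns
    contribute no edges."""
    ranks = stats.rankdata(values, axis=0)
    constant = ranks.std(axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.nan_to_num(np.atleast_2d(rho), nan=0.0)
    if constant.any():
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
    iu = np.triu_indices(rho.shape[0], k=1)
    return int(np.count_nonzero(np.abs(rho[iu]) >= tau))


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    alternative: str
    tau: float
    n_permutations: int
    null: np.ndarray = field(repr=False)


def permutation_edge_test(
    mat_a: MarkerMatrix,
    mat_b: MarkerMatrix,
    tau: float,
    n_permutations: int = 10_000,
    seed: int | None = None,
    alternative: str = "greater",
    exact: bool = False,
) -> PermutationResult:
    """Permutation test for a difference in network edge counts.

    The observed statistic is ``edges(b) - edges(a)`` with both networks
    thresholded at the same fixed ``tau`` (the cutoff selected on the
    observed data; it is *not* re-selected per permutation). The null is
    built by reassigning pooled samples to the two groups at random,
    preserving group sizes. The p-value is ``(b + 1) / (B + 1)`` with ``b``
    the number of permuted statistics at least as extreme as the observed
    one in the direction of ``alternative`` ("greater", "less" or
    "two-sided"); it is therefore never 0.

    With ``exact=True`` all distinct assignments of pooled samples to group
    A are enumerated instead of sampled (small cohorts only).
    """
    if mat_a.marker_ids != mat_b.marker_ids:
        raise ParameterError("marker panels differ between the two groups")
    if alternative not in ("greater", "less", "two-sided"):
        raise ParameterError(f"unknown alternative {alternative!r}")
    if not 0 < tau <= 1:
        raise ParameterError(f"tau must be in (0, 1], got {tau}")
    a = mat_a.values_for()
    b = mat_b.values_for()
    n_a, n_b = a.shape[0], b.shape[0]
    pooled = np.vstack([a, b])
    observed = _edge_count(b, tau) - _edge_count(a, tau)

    null = []
    if exact:
        for idx_a in combinations(range(n_a + n_b), n_a):
            mask = np.zeros(n_a + n_b, dtype=bool)
            mask[list(idx_a)] = True
            null.append(_edge_count(pooled[~mask], tau) - _edge_count(pooled[mask], tau))
    else:
        if n_permutations < 1:
            raise ParameterError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        order = np.arange(n_a + n_b)
        for _ in range(n_permutations):
            rng.shuffle(order)
            null.append(
                _edge_count(pooled[order[n_a:]], tau)
                - _edge_count(pooled[order[:n_a]], tau)
            )
    null_arr = np.asarray(null, dtype=float)
    if alternative == "greater":
        extreme = np.count_nonzero(null_arr >= observed)
    elif alternative == "less":
        extreme = np.count_nonzero(null_arr <= observed)
    else:
        extreme = np.count_nonzero(np.abs(null_arr) >= abs(observed))
    p = (extreme + 1) / (len(null_arr) + 1)
    return PermutationResult(float(observed), float(p), alternative, float(tau), len(null_arr), null_arr)


def ks_degree_test(
    summary_a: NetworkSummary | list[int],
    summary_b: NetworkSummary | list[int],
    exact: bool = False,
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on two degree distributions.

    Uses the asymptotic two-sided p by default (degree samples here have
    tens of points); ``exact=True`` switches to the exact small-sample
    distribution. Accepts network summaries or raw degree sequences.
    """
    deg_a = list(summary_a.degrees.values()) if isinstance(summary_a, NetworkSummary) else list(summary_a)
    deg_b = list(summary_b.degrees.values()) if isinstance(summary_b, NetworkSummary) else list(summary_b)
    if not deg_a or not deg_b:
        raise ParameterError("empty degree sample")
    res = stats.ks_2samp(deg_a, deg_b, method="exact" if exact else "asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class HubOverlap:
    shared: set[str]
    a_only: set[str]
    b_only: set[str]
    shared_differential: set[str]
    a_differential: set[str]
    b_differential: set[str]

    def counts(self) -> dict[str, int]:
        return {k: len(getattr(self, k)) for k in (
            "shared", "a_only", "b_only",
            "shared_differential", "a_differential", "b_differential")}


def _names(hubs) -> set[str]:
    return {h[0] if isinstance(h, tuple) else h for h in hubs}


def hub_overlap(hubs_a, hubs_b, differential=()) -> HubOverlap:
    """Partition two hub sets and intersect each part with a differential
    marker list (hub lists may be ``detect_hubs`` output or plain names)."""
    a, b = _names(hubs_a), _names(hubs_b)
    diff = set(differential)
    return HubOverlap(
        shared=a & b,
        a_only=a - b,
        b_only=b - a,
        shared_differential=a & b & diff,
        a_differential=a & diff,
        b_differential=b & diff,
    )
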