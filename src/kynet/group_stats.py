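"""Between-group marker comparisons, kynurenine ratio indices, and PCA.

Group comparisons use a two-sample t-test per marker (Welch by default —
the small groups show clearly unequal spread — pooled-variance Student's t
by flag) with Bonferroni correction: corrected p = min(1, raw p x m), where
m defaults to the number of markers tested in the comparison.

Ratio indices capture pathway enzyme activity from metabolite
concentrations: KYN:TRP indexes IDO activity, 3-HK/KYN the KMO branch, and
XA/3-HK transamination of 3-HK toward xanthurenic acid. Ratios require the
canonical nM scale; samples with a non-positive denominator are flagged
undefined and excluded from the group mean, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .datatypes import MarkerMatrix, ParameterError, RatioIndex, concat_groups

__all__ = [
    "ComparisonResult",
    "compare_groups",
    "DEFAULT_RATIOS",
    "compute_ratio_indices",
    "pca_scores",
]

#: Pathway activity indices computed by default.
DEFAULT_RATIOS = [
    RatioIndex("KYN:TRP", "KYN", "TRP"),
    RatioIndex("3-HK/KYN", "3-HK", "KYN"),
    RatioIndex("XA/3-HK", "XA", "3-HK"),
]


@dataclass
class ComparisonResult:
    """Per-marker two-group test results (one published-table-style row each)."""

    comparison: str
    table: pd.DataFrame
    m_comparisons: int
    flagged: list[str] = field(default_factory=list)


def _mean_ci(x: np.ndarray) -> tuple[float, float, float]:
    n = len(x)
    mean = float(np.mean(x))
    if n < 2:
        return mean, mean, mean
    half = stats.t.ppf(0.975, n - 1) * np.std(x, ddof=1) / np.sqrt(n)
    return mean, mean - float(half), mean + float(half)


def compare_groups(
    mat_a: MarkerMatrix,
    mat_b: MarkerMatrix,
    markers: list[str] | None = None,
    m_comparisons: int | None = None,
    welch: bool = True,
    label: str | None = None,
) -> ComparisonResult:
    """Two-sample t-test per marker with Bonferroni-corrected p-values.

    ``m_comparisons`` defaults to the number of markers tested. Markers with
    zero variance in both groups have no defined t statistic; they are
    reported with NaN statistic/p and listed in ``flagged``.
    """
    cols = mat_a.marker_ids if markers is None else list(markers)
    a = mat_a.values_for(cols)
    b = mat_b.values_for(cols)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ParameterError("each group needs >= 2 samples")
    m = len(cols) if m_comparisons is None else int(m_comparisons)
    if m < 1:
        raise ParameterError("m_comparisons must be >= 1")
    ga = str(mat_a.groups.iloc[0])
    gb = str(mat_b.groups.iloc[0])
    label = label or f"{ga} vs {gb}"

    rows = []
    flagged = []
    for j, marker in enumerate(cols):
        xa, xb = a[:, j], b[:, j]
        mean_a, lo_a, hi_a = _mean_ci(xa)
        mean_b, lo_b, hi_b = _mean_ci(xb)
        if np.var(xa) == 0 and np.var(xb) == 0:
            t_stat, p_raw, p_corr = np.nan, np.nan, np.nan
            if mean_a == mean_b:
                # identical constants: no evidence of difference
                t_stat, p_raw, p_corr = 0.0, 1.0, 1.0
            else:
                flagged.append(marker)
        else:
            res = stats.ttest_ind(xa, xb, equal_var=not welch)
            t_stat, p_raw = float(res.statistic), float(res.pvalue)
            p_corr = min(1.0, p_raw * m)
        rows.append(
            {
                "marker": marker,
                "mean_a": mean_a, "ci_lo_a": lo_a, "ci_hi_a": hi_a,
                "mean_b": mean_b, "ci_lo_b": lo_b, "ci_hi_b": hi_b,
                "t": t_stat, "p_raw": p_raw, "p_corrected": p_corr,
            }
        )
    table = pd.DataFrame(rows).set_index("marker")
    return ComparisonResult(label, table, m, flagged)


def compute_ratio_indices(
    mat: MarkerMatrix,
    indices: list[RatioIndex] | None = None,
) -> pd.DataFrame:
    """Per-sample ratio values plus per-group means.

    Input concentrations must be on a common scale; the matrix is normalized
    to nM first. Samples where the denominator is <= 0 get NaN and are
    counted per ratio in the result's ``attrs['n_undefined']``; group means
    are computed over the remaining samples with a warning.
    """
    indices = DEFAULT_RATIOS if indices is None else indices
    mat = mat.to_canonical_units()
    missing = {
        m
        for idx in indices
        for m in (idx.numerator, idx.denominator)
        if m not in mat.data.columns
    }
    if missing:
        raise ParameterError(f"ratio markers not in table: {sorted(missing)}")
    out = pd.DataFrame(index=mat.data.index)
    out["group"] = mat.groups
    n_undef: dict[str, int] = {}
    for idx in indices:
        num = mat.data[idx.numerator].to_numpy(dtype=float)
        den = mat.data[idx.denominator].to_numpy(dtype=float)
        bad = den <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(bad, np.nan, num / np.where(bad, np.nan, den))
        n_undef[idx.name] = int(bad.sum())
        if bad.any():
            warnings.warn(
                f"ratio {idx.name}: {int(bad.sum())} sample(s) with denominator <= 0 "
                "excluded from group means",
                stacklevel=2,
            )
        out[idx.name] = vals
    out.attrs["n_undefined"] = n_undef
    out.attrs["group_means"] = out.groupby("group", sort=False).mean(numeric_only=True)
    return out


def pca_scores(
    mats: list[MarkerMatrix],
    n_components: int = 2,
    scale: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the pooled samples for confounder screening.

    Markers are centered and (by default) scaled to unit variance before the
    singular value decomposition — the panels mix nM and NPX-log2 scales.
    Constant markers cannot be autoscaled and are dropped with a warning.
    Returns (scores frame with a ``group`` column, explained-variance
    fractions).
    """
    pooled = concat_groups(mats) if len(mats) > 1 else mats[0]
    if pooled.n_samples < 3:
        raise ParameterError("need >= 3 pooled samples for PCA")
    x = pooled.data.to_numpy(dtype=float)
    keep = np.ones(x.shape[1], dtype=bool)
    if scale:
        sd = x.std(axis=0)
        keep = sd > 0
        if not keep.all():
            dropped = [m for m, k in zip(pooled.marker_ids, keep) if not k]
            warnings.warn(f"constant markers dropped before scaling: {dropped}", stacklevel=2)
        x = (x[:, keep] - x[:, keep].mean(axis=0)) / x[:, keep].std(axis=0)
    else:
        x = x - x.mean(axis=0)
    k = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    frame = pd.DataFrame(
        scores, index=pooled.data.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    frame["group"] = pooled.groups
    return frame, pca.explained_variance_ratio_
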