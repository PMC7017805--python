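"""Synthetic plasma-marker cohorts with controllable correlation structure.

The generator emulates the statistical shape of a small melanoma
immunometabolism study: three groups (healthy controls, patients before
treatment, patients during MAPK-inhibitor treatment) of five plasma samples
each, a seven-analyte kynurenine-pathway metabolite (KPM) panel measured in
concentration units, and a 92-marker immuno-oncology protein panel on the
NPX log2 scale.

Sampling uses a Gaussian copula: a latent multivariate normal draw with a
block-structured correlation matrix is pushed through each marker's marginal
distribution (zero-truncated normal for concentrations, normal for NPX
values). Because the downstream analysis is rank-based, the copula makes the
target dependence structure scale-free: the implied Spearman correlation of
a latent Pearson correlation r is ``(6/pi) * arcsin(r/2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MarkerMatrix, ParameterError

__all__ = [
    "GroupMarginal",
    "MetaboliteSpec",
    "CohortSpec",
    "default_metabolite_panel",
    "build_block_correlation",
    "implied_spearman",
    "generate_cohort",
]

# 95% CI half-width of a mean of n=5 equals t(0.975, 4) * sd / sqrt(5).
_T975_DF4 = stats.t.ppf(0.975, 4)

# Published group means and 95% CIs for the seven-metabolite plasma panel
# (healthy controls, pre-treatment and on-treatment melanoma patients,
# n = 5 per group). Units are mixed exactly as reported.
_PANEL_TABLE: list[tuple[str, str, dict[str, tuple[float, float, float]]]] = [
    ("TRP", "uM", {"HC": (42.04, 35.9, 48.2), "PRE": (45.4, 34.0, 58.7), "TRM": (42.98, 31.2, 54.7)}),
    ("KYN", "uM", {"HC": (2.66, 2.1, 3.3), "PRE": (3.54, 1.8, 5.2), "TRM": (9.78, 6.6, 12.9)}),
    ("KYNA", "nM", {"HC": (38.11, 26.0, 50.2), "PRE": (43.45, 24.0, 55.1), "TRM": (27.57, 19.8, 35.4)}),
    ("3-HK", "nM", {"HC": (195.30, 162.6, 228.0), "PRE": (73.23, 21.9, 111.2), "TRM": (324.9, 295.6, 354.2)}),
    ("3HAA", "nM", {"HC": (372.28, 360.3, 384.3), "PRE": (147.96, 77.9, 218.0), "TRM": (804.47, 751.2, 857.8)}),
    ("AA", "nM", {"HC": (23.10, 17.9, 28.3), "PRE": (28.51, 13.1, 40.5), "TRM": (43.85, 35.4, 52.3)}),
    ("XA", "nM", {"HC": (73.51, 52.0, 95.0), "PRE": (57.23, 25.8, 77.8), "TRM": (88.51, 62.1, 115.0)}),
]

METABOLITE_NAMES = [name for name, _, _ in _PANEL_TABLE]


@dataclass(frozen=True)
class GroupMarginal:
    """Marginal distribution of one marker in one group."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ParameterError(f"standard deviation must be > 0, got {self.sd}")


@dataclass(frozen=True)
class MetaboliteSpec:
    """Name, unit and per-group (mean, sd) of a concentration marker."""

    name: str
    unit: str
    marginals: dict[str, GroupMarginal]


def _sd_from_ci(lo: float, hi: float, n: int = 5) -> float:
    # The source table prints means with 95% CIs but no dispersions; invert
    # the t-interval half-width (hi - lo)/2 = t * sd / sqrt(n).
    return (hi - lo) / 2.0 * math.sqrt(n) / _T975_DF4


def default_metabolite_panel() -> list[MetaboliteSpec]:
    """The 7-metabolite KPM panel calibrated to the published group table."""
    panel = []
    for name, unit, per_group in _PANEL_TABLE:
        marginals = {
            g: GroupMarginal(mean=mean, sd=_sd_from_ci(lo, hi))
            for g, (mean, lo, hi) in per_group.items()
        }
        panel.append(MetaboliteSpec(name=name, unit=unit, marginals=marginals))
    return panel


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``blocks`` partitions *all* markers (metabolites + proteins) into
    correlation blocks: latent correlation is ``r_within`` inside a block and
    ``r_between`` across blocks. Protein markers share a common NPX marginal
    (mean ``protein_npx_mean``, sd ``protein_npx_sd``) in every group unless
    ``protein_group_shift`` adds a per-group mean offset.
    """

    group_names: list[str] = field(default_factory=lambda: ["HC", "PRE", "TRM"])
    n_per_group: int = 5
    metabolite_panel: list[MetaboliteSpec] = field(default_factory=default_metabolite_panel)
    n_proteins: int = 92
    blocks: list[list[str]] | None = None
    r_within: float = 0.5
    r_between: float = 0.1
    seed: int = 0
    protein_npx_mean: float = 6.0
    protein_npx_sd: float = 1.0
    protein_group_shift: dict[str, float] = field(default_factory=dict)
    paired_groups: tuple[str, ...] = ("PRE", "TRM")
    patient_effect_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ParameterError("n_per_group must be positive")
        if not (0 <= self.r_between <= self.r_within < 1):
            raise ParameterError(
                "require 0 <= r_between <= r_within < 1 "
                f"(got r_within={self.r_within}, r_between={self.r_between})")
        for spec in self.metabolite_panel:
            missing = set(self.group_names) - set(spec.marginals)
            if missing:
                raise ParameterError(f"metabolite {spec.name} lacks marginals for {sorted(missing)}")
        if self.blocks is None:
            # Default world: metabolites form one co-regulated block, the
            # protein panel a second.
            self.blocks = [
                [m.name for m in self.metabolite_panel],
                list(self.protein_ids),
            ]
            self.blocks = [b for b in self.blocks if b]
        flat = [m for b in self.blocks for m in b]
        if sorted(flat) != sorted(self.marker_ids):
            raise ParameterError("blocks must partition all markers exactly once")

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.name for m in self.metabolite_panel]

    @property
    def protein_ids(self) -> list[str]:
        width = len(str(max(self.n_proteins, 1)))
        return [f"PROT{str(i + 1).zfill(width)}" for i in range(self.n_proteins)]

    @property
    def marker_ids(self) -> list[str]:
        return self.metabolite_ids + self.protein_ids

    @property
    def units(self) -> dict[str, str]:
        units = {m.name: m.unit for m in self.metabolite_panel}
        units.update({p: "NPX" for p in self.protein_ids})
        return units


def build_block_correlation(
    blocks: list[list[str]],
    r_within: float,
    r_between: float,
    psd_floor: float = 1e-10,
) -> pd.DataFrame:
    """Block-structured correlation matrix: ``r_within`` inside a block,
    ``r_between`` across blocks, unit diagonal.

    If the raw matrix is not positive semi-definite (possible when
    ``r_between`` is close to ``r_within``), negative eigenvalues are clipped
    to ``psd_floor`` and the matrix renormalized to unit diagonal.
    """
    if not (0 <= r_between <= r_within < 1):
        raise ParameterError(
            f"require 0 <= r_between <= r_within < 1, got {r_within=}, {r_between=}")
    markers = [m for b in blocks for m in b]
    if len(set(markers)) != len(markers):
        raise ParameterError("a marker appears in more than one block")
    p = len(markers)
    corr = np.full((p, p), r_between, dtype=float)
    offset = 0
    for b in blocks:
        k = len(b)
        corr[offset:offset + k, offset:offset + k] = r_within
        offset += k
    np.fill_diagonal(corr, 1.0)
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] < 0:
        corr = _psd_repair(corr, psd_floor)
    return pd.DataFrame(corr, index=markers, columns=markers)


def _psd_repair(corr: np.ndarray, floor: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, floor, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def implied_spearman(r_latent: float) -> float:
    """Spearman correlation implied by latent Gaussian correlation ``r``."""
    return 6.0 / math.pi * math.asin(r_latent / 2.0)


def _truncated_normal_from_uniform(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    # Inverse-CDF transform onto a normal truncated at zero. Equivalent in
    # distribution to redraw-until-nonnegative, but rank-preserving so the
    # copula's Spearman targets survive the margin transform.
    a = (0.0 - mean) / sd
    return stats.truncnorm.ppf(u, a=a, b=np.inf, loc=mean, scale=sd)


def generate_cohort(spec: CohortSpec) -> dict[str, MarkerMatrix]:
    """Draw one MarkerMatrix per group, all sharing the same marker panel.

    A single RNG stream seeded from ``spec.seed`` drives the whole call, so
    identical specs give bit-identical cohorts. Groups listed in
    ``spec.paired_groups`` share patient ids (same index within group); when
    ``patient_effect_sd > 0`` those groups also share a per-patient latent
    offset, rescaled so latent margins stay standard normal.
    """
    rng = np.random.default_rng(spec.seed)
    corr = build_block_correlation(spec.blocks, spec.r_within, spec.r_between)
    corr = corr.loc[spec.marker_ids, spec.marker_ids]
    try:
        chol = np.linalg.cholesky(corr.to_numpy() + 1e-12 * np.eye(len(spec.marker_ids)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - repair failed
        raise ParameterError(f"correlation matrix not usable after PSD repair: {exc}")

    n, p = spec.n_per_group, len(spec.marker_ids)
    metab = {m.name: m for m in spec.metabolite_panel}

    patient_offset = None
    if spec.patient_effect_sd > 0 and spec.paired_groups:
        patient_offset = rng.standard_normal((n, p)) * spec.patient_effect_sd

    out: dict[str, MarkerMatrix] = {}
    for group in spec.group_names:
        z = rng.standard_normal((n, p)) @ chol.T
        if patient_offset is not None and group in spec.paired_groups:
            z = (z + patient_offset) / math.sqrt(1.0 + spec.patient_effect_sd ** 2)
        u = stats.norm.cdf(z)
        # guard exact 0/1 from finite-precision tails
        u = np.clip(u, 1e-12, 1 - 1e-12)
        values = np.empty((n, p), dtype=float)
        for j, marker in enumerate(spec.marker_ids):
            if marker in metab:
                marg = metab[marker].marginals[group]
                values[:, j] = _truncated_normal_from_uniform(u[:, j], marg.mean, marg.sd)
            else:
                mu = spec.protein_npx_mean + spec.protein_group_shift.get(group, 0.0)
                values[:, j] = mu + spec.protein_npx_sd * z[:, j]
        sample_ids = [f"{group}_{i + 1:03d}" for i in range(n)]
        data = pd.DataFrame(values, index=sample_ids, columns=spec.marker_ids)
        groups = pd.Series(group, index=sample_ids)
        patients = None
        if group in spec.paired_groups:
            patients = pd.Series([f"P{i + 1:03d}" for i in range(n)], index=sample_ids)
        classes = {m: ("metabolite" if m in metab else "protein") for m in spec.marker_ids}
        out[group] = MarkerMatrix(data, groups, spec.units, patients, classes)
    return out
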