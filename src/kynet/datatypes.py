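"""Core data containers shared by every analysis stage.

A :class:`MarkerMatrix` is the single currency of the pipeline: a samples x
markers table of plasma measurements (kynurenine-pathway metabolites in
nM/µM, immune proteins on the NPX log2 scale) together with per-sample group
labels and, for paired pre-/during-treatment designs, patient identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: Recognized measurement units. "NPX" is the unitless log2 scale of
#: proximity extension assays; "nM" is the canonical concentration unit.
VALID_UNITS = ("nM", "uM", "NPX")

#: Exact conversion factors to the canonical concentration unit (nM).
TO_NM = {"nM": 1.0, "uM": 1000.0}


class FormatError(ValueError):
    """Malformed input table or unknown serialization format."""


class ParameterError(ValueError):
    """Invalid argument to an analysis operation."""


def normalize_unit(unit: str) -> str:
    u = unit.strip().replace("µ", "u").replace("μ", "u")
    if u in ("uM", "um", "UM"):
        return "uM"
    if u in ("nM", "nm", "NM"):
        return "nM"
    if u.upper() == "NPX":
        return "NPX"
    raise FormatError(f"unknown unit {unit!r}; expected one of {VALID_UNITS}")


@dataclass
class MarkerMatrix:
    """Samples x markers measurement table for one (or more) groups.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with one numeric column per marker.
    groups
        Group label per sample (e.g. ``HC``, ``PRE``, ``TRM``), aligned to
        ``data.index``.
    units
        Unit per marker: ``nM``, ``uM`` or ``NPX``.
    patients
        Optional patient id per sample, used to pair PRE with TRM draws from
        the same individual. ``None`` entries mean unpaired (e.g. controls).
    """

    data: pd.DataFrame
    groups: pd.Series
    units: dict[str, str]
    patients: pd.Series | None = None
    marker_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate marker ids")
        self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            missing = list(self.data.index[self.groups.isna()])
            raise FormatError(f"missing group label for samples {missing}")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise FormatError("non-finite values in marker table")
        self.units = {m: normalize_unit(u) for m, u in self.units.items()}
        unknown = set(self.data.columns) - set(self.units)
        if unknown:
            raise FormatError(f"markers without units: {sorted(unknown)}")
        if self.patients is not None:
            self.patients = self.patients.reindex(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def to_canonical_units(self) -> "MarkerMatrix":
        """Convert every concentration column to nM; NPX columns untouched.

        Conversion is exact (µM -> nM is x1000) so ratio indices computed on
        mixed-unit inputs equal those computed on native-nM inputs.
        """
        data = self.data.copy()
        units = {}
        for m in data.columns:
            u = self.units[m]
            if u == "NPX":
                units[m] = "NPX"
                continue
            data[m] = data[m] * TO_NM[u]
            units[m] = "nM"
        conc = [m for m, u in units.items() if u == "nM"]
        if conc and (data[conc].to_numpy() < 0).any():
            raise FormatError("negative concentration after unit normalization")
        return MarkerMatrix(data, self.groups.copy(), units,
                            None if self.patients is None else self.patients.copy(),
                            dict(self.marker_class))

    def subset_group(self, group: str) -> "MarkerMatrix":
        mask = self.groups == group
        if not mask.any():
            raise ParameterError(f"no samples with group label {group!r}")
        return MarkerMatrix(
            self.data.loc[mask].copy(), self.groups[mask].copy(), dict(self.units),
            None if self.patients is None else self.patients[mask].copy(),
            dict(self.marker_class))

    def values_for(self, markers: list[str] | None = None) -> np.ndarray:
        cols = self.marker_ids if markers is None else list(markers)
        missing = set(cols) - set(self.data.columns)
        if missing:
            raise ParameterError(f"markers not in table: {sorted(missing)}")
        return self.data[cols].to_numpy(dtype=float)


def concat_groups(mats: list["MarkerMatrix"]) -> "MarkerMatrix":
    """Stack per-group matrices sharing the same marker panel."""
    if not mats:
        raise ParameterError("no matrices to concatenate")
    cols = mats[0].marker_ids
    for m in mats[1:]:
        if m.marker_ids != cols:
            raise ParameterError("marker panels differ between matrices")
    data = pd.concat([m.data for m in mats])
    groups = pd.concat([m.groups for m in mats])
    pats = None
    if any(m.patients is not None for m in mats):
        pats = pd.concat([
            m.patients if m.patients is not None
            else pd.Series([None] * m.n_samples, index=m.data.index)
            for m in mats])
    units = dict(mats[0].units)
    classes: dict[str, str] = {}
    for m in mats:
        classes.update(m.marker_class)
    return MarkerMatrix(data, groups, units, pats, classes)


@dataclass
class CorrelationMatrix:
    """Symmetric marker x marker Spearman rho matrix for one group."""

    marker_ids: list[str]
    rho: np.ndarray
    n_samples: int
    constant_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        p = len(self.marker_ids)
        if r.shape != (p, p):
            raise ParameterError("rho shape does not match marker_ids")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ParameterError("rho not symmetric")
        if np.nanmax(np.abs(r)) > 1 + 1e-9:
            raise ParameterError("|rho| > 1")
        self.rho = r

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.marker_ids, columns=self.marker_ids)


@dataclass
class MarkerNetwork:
    """Undirected correlation network over markers at a fixed cutoff.

    Nodes are markers with at least one retained edge; each edge carries the
    signed Spearman rho as ``weight`` and satisfies ``|rho| >= threshold``.
    """

    graph: nx.Graph
    threshold: float
    group: str = ""

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())


@dataclass
class NetworkSummary:
    """Topology summary of one marker network: the network-characteristics row set."""

    group: str
    n_nodes: int
    n_edges: int
    median_degree: float
    avg_clustering: float
    hubs: list[tuple[str, int]]
    degrees: dict[str, int]

    def as_frame(self) -> pd.DataFrame:
        hub_str = "; ".join(f"{h}({d})" for h, d in self.hubs)
        return pd.DataFrame(
            {
                "group": [self.group],
                "n_nodes": [self.n_nodes],
                "n_edges": [self.n_edges],
                "median_degree": [self.median_degree],
                "avg_clustering": [self.avg_clustering],
                "hubs": [hub_str],
            }
        )


@dataclass
class RatioIndex:
    """A named metabolite ratio, e.g. KYN:TRP as the IDO-activity index."""

    name: str
    numerator: str
    denominator: str
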