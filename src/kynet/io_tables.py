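"""Reading/writing marker tables and exporting networks.

Tables are delimited text (TSV primary, CSV accepted) with one row per
sample: a ``sample_id`` column, a ``group`` column, an optional
``patient_id`` column, and one numeric column per marker. Units are never
guessed from the table; they come from a schema mapping marker -> unit
(``nM``, ``uM`` or ``NPX``), optionally with a marker class
(metabolite/protein). Concentrations are normalized to nM at load so that
downstream ratio indices are unit-safe.

Networks export to GraphML (with rho edge weights and node attributes) or
SIF, the three-column Cytoscape interaction format.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import FormatError, MarkerMatrix, MarkerNetwork, ParameterError, normalize_unit

__all__ = [
    "read_schema",
    "write_schema",
    "read_marker_table",
    "write_marker_table",
    "export_network",
    "read_graphml",
]

_META_COLS = ("sample_id", "group", "patient_id")


def read_schema(path: str | Path) -> dict[str, dict[str, str]]:
    """Load a JSON schema: ``{marker: {"unit": ..., "class": ...}}``.

    A flat ``{marker: unit}`` form is also accepted.
    """
    with open(path) as fh:
        raw = json.load(fh)
    schema: dict[str, dict[str, str]] = {}
    for marker, val in raw.items():
        if isinstance(val, str):
            schema[marker] = {"unit": normalize_unit(val)}
        else:
            entry = {"unit": normalize_unit(val["unit"])}
            if "class" in val:
                entry["class"] = val["class"]
            schema[marker] = entry
    return schema


def write_schema(mat: MarkerMatrix, path: str | Path) -> None:
    schema = {}
    for m in mat.marker_ids:
        entry: dict[str, str] = {"unit": mat.units[m]}
        if m in mat.marker_class:
            entry["class"] = mat.marker_class[m]
        schema[m] = entry
    with open(path, "w") as fh:
        json.dump(schema, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _sniff_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if "\t" in header else ","


def read_marker_table(
    path: str | Path,
    schema: dict[str, dict[str, str]] | dict[str, str],
    normalize: bool = True,
) -> MarkerMatrix:
    """Parse a delimited marker table into a :class:`MarkerMatrix`.

    Rows with unparseable numerics are rejected with a row-addressed error;
    markers absent from the schema, duplicate sample ids and missing group
    labels are format errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise FormatError(f"{path}: need 'sample_id' and 'group' columns")
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    if df["group"].isna().any():
        rows = (df.index[df["group"].isna()] + 2).tolist()  # +2: header + 1-based
        raise FormatError(f"{path}: missing group label at line(s) {rows}")

    markers = [c for c in df.columns if c not in _META_COLS]
    norm_schema: dict[str, dict[str, str]] = {
        m: ({"unit": v} if isinstance(v, str) else dict(v)) for m, v in schema.items()
    }
    unknown = set(markers) - set(norm_schema)
    if unknown:
        raise FormatError(f"{path}: markers missing from schema: {sorted(unknown)}")

    values = pd.DataFrame(index=df["sample_id"])
    for m in markers:
        # exact strtod via float(); pandas' fast csv parser can be 1 ulp off
        parsed, bad_lines = [], []
        for row, raw in enumerate(df[m]):
            try:
                parsed.append(float(raw))
            except (TypeError, ValueError):
                parsed.append(np.nan)
                bad_lines.append(row + 2)  # +2: header + 1-based
        if bad_lines:
            raise FormatError(
                f"{path}: unparseable value for marker {m!r} at line(s) {bad_lines}")
        values[m] = np.asarray(parsed)

    units = {m: normalize_unit(norm_schema[m]["unit"]) for m in markers}
    classes = {m: norm_schema[m]["class"] for m in markers if "class" in norm_schema[m]}
    groups = pd.Series(df["group"].to_numpy(), index=df["sample_id"])
    patients = None
    if "patient_id" in df.columns:
        patients = pd.Series(df["patient_id"].to_numpy(), index=df["sample_id"])
    mat = MarkerMatrix(values, groups, units, patients, classes)
    return mat.to_canonical_units() if normalize else mat


def write_marker_table(mat: MarkerMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a marker table; round-trips bit-identically through ``read_marker_table``
    (with ``normalize=False``) via full-precision ``repr`` formatting."""
    path = Path(path)
    out = pd.DataFrame({"sample_id": mat.sample_ids, "group": mat.groups.to_numpy()})
    if mat.patients is not None:
        out["patient_id"] = mat.patients.to_numpy()
    for m in mat.marker_ids:
        out[m] = [repr(float(v)) for v in mat.data[m]]
    out.to_csv(path, sep=sep, index=False)


def export_network(net: MarkerNetwork, fmt: str, path: str | Path) -> None:
    """Export a marker network as GraphML or SIF.

    GraphML carries the signed rho as edge ``weight`` plus node attributes
    (``marker_class``, ``hub`` flag when present). SIF records one line per
    edge with interaction type ``corr``; isolated nodes do not occur by
    construction.
    """
    if net.n_nodes < 1:
        raise ParameterError("refusing to export an empty network")
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.graph, path, named_key_ids=True)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(net.graph.edges()):
                fh.write(f"{u}\tcorr\t{v}\n")
    else:
        raise ParameterError(f"unknown export format {fmt!r}; use 'graphml' or 'sif'")


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
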