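"""One-command orchestration of the full analysis.

``run_pipeline`` binds the stages in analysis order: obtain a cohort
(simulate one or load marker tables), run group statistics (metabolite
comparisons, ratio indices, PCA screening), infer the per-group correlation
networks with a shared fragmentation-selected cutoff, compare the networks
(permutation edge test, K-S degree test, hub overlap), and write a
deterministic report bundle. Given the same config and seed the bundle is
byte-identical across runs; wall-clock timings go to the log stream only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datatypes import FormatError, MarkerMatrix, ParameterError, concat_groups
from .group_stats import compare_groups, compute_ratio_indices, pca_scores
from .io_tables import export_network, read_marker_table, read_schema, write_marker_table, write_schema
from .network_compare import hub_overlap, ks_degree_test, permutation_edge_test
from .network_inference import (
    build_network,
    default_grid,
    select_threshold,
    spearman_matrix,
    summarize_network,
)
from .synthetic_cohort import CohortSpec, generate_cohort

__all__ = ["RunConfig", "StageError", "run_pipeline"]

log = logging.getLogger("kynet")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Plain-text-serializable pipeline configuration."""

    seed: int = 0
    outdir: str = "kynet_out"
    simulate: dict = field(default_factory=dict)  # CohortSpec overrides; {} = defaults
    input_tables: list[str] = field(default_factory=list)
    input_schema: str | None = None
    comparisons: list[list[str]] = field(default_factory=lambda: [["HC", "PRE"], ["PRE", "TRM"]])
    comparison_markers: list[str] | None = None  # default: metabolite panel
    m_comparisons: int | None = None
    network_groups: list[str] = field(default_factory=lambda: ["PRE", "TRM"])
    grid_start: float = 0.95
    grid_stop: float = 0.05
    grid_step: float = 0.05
    strict_connectivity: bool = False
    hub_percentile: float = 80.0
    n_permutations: int = 1000
    differential_alpha: float = 0.05
    welch: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def analysis_dict(self) -> dict:
        # everything that affects results; outdir only affects where they go
        d = self.to_dict()
        d.pop("outdir")
        return d

    def digest(self) -> str:
        payload = json.dumps(self.analysis_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def _load_cohort(config: RunConfig, outdir: Path) -> dict[str, MarkerMatrix]:
    if config.input_tables:
        if config.input_schema is None:
            raise StageError("load", "input_tables given without input_schema")
        schema = read_schema(config.input_schema)
        groups: dict[str, MarkerMatrix] = {}
        for path in config.input_tables:
            mat = read_marker_table(path, schema)
            for g in mat.groups.unique():
                if g in groups:
                    raise StageError("load", f"group {g} appears in more than one table")
                groups[g] = mat.subset_group(g)
        return groups
    spec = CohortSpec(seed=config.seed, **config.simulate)
    cohort = generate_cohort(spec)
    for g, mat in cohort.items():
        write_marker_table(mat, outdir / f"cohort_{g}.tsv")
    write_schema(next(iter(cohort.values())), outdir / "schema.json")
    return {g: m.to_canonical_units() for g, m in cohort.items()}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle into ``config.outdir``.

    Returns a dict with the in-memory results (cohort, comparison tables,
    network summaries, comparison report). Any stage error aborts with the
    stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    results: dict = {"config": config}

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        with _stage("load"):
            try:
                cohort = _load_cohort(config, outdir)
            except (ParameterError, FormatError) as exc:
                raise StageError("load", str(exc))
            results["cohort"] = cohort

        with _stage("stats"):
            try:
                comparisons = {}
                for pair in config.comparisons:
                    a, b = pair
                    if a not in cohort or b not in cohort:
                        raise ParameterError(f"comparison group missing from cohort: {pair}")
                    markers = config.comparison_markers
                    if markers is None:
                        markers = [
                            m for m in cohort[a].marker_ids
                            if cohort[a].marker_class.get(m) == "metabolite"
                        ] or cohort[a].marker_ids
                    res = compare_groups(
                        cohort[a], cohort[b], markers,
                        m_comparisons=config.m_comparisons, welch=config.welch)
                    comparisons[f"{a}_vs_{b}"] = res
                    res.table.to_csv(outdir / f"comparison_{a}_vs_{b}.tsv", sep="\t")
                results["comparisons"] = comparisons

                metab_any = any(
                    cohort[g].marker_class.get(m) == "metabolite"
                    for g in cohort for m in cohort[g].marker_ids)
                if metab_any:
                    pooled = concat_groups(list(cohort.values()))
                    ratios = compute_ratio_indices(pooled)
                    ratios.to_csv(outdir / "ratios.tsv", sep="\t")
                    ratios.attrs["group_means"].to_csv(outdir / "ratio_group_means.tsv", sep="\t")
                    results["ratios"] = ratios
                scores, evr = pca_scores(list(cohort.values()))
                scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
                results["pca"] = (scores, evr)
            except (ParameterError, FormatError) as exc:
                raise StageError("stats", str(exc))

        with _stage("network"):
            try:
                net_groups = [g for g in config.network_groups if g in cohort]
                if not net_groups:
                    raise ParameterError(
                        f"none of network_groups {config.network_groups} in cohort")
                grid = default_grid(config.grid_start, config.grid_stop, config.grid_step)
                corrs = {g: spearman_matrix(cohort[g]) for g in net_groups}
                # cutoff selected on the first network group, applied to all
                tau = select_threshold(corrs[net_groups[0]], grid, config.strict_connectivity)
                networks, summaries = {}, {}
                for g in net_groups:
                    net = build_network(corrs[g], tau, group=g)
                    networks[g] = net
                    summaries[g] = summarize_network(net, config.hub_percentile)
                    if net.n_nodes:
                        hubs = {h for h, _ in summaries[g].hubs}
                        for node in net.graph.nodes:
                            net.graph.nodes[node]["hub"] = node in hubs
                            net.graph.nodes[node]["marker_class"] = (
                                cohort[g].marker_class.get(node, ""))
                        export_network(net, "graphml", outdir / f"network_{g}.graphml")
                pd.concat([s.as_frame() for s in summaries.values()]).to_csv(
                    outdir / "network_summary.tsv", sep="\t", index=False)
                results.update(threshold=tau, networks=networks, summaries=summaries)
            except (ParameterError, FormatError) as exc:
                raise StageError("network", str(exc))

        with _stage("compare"):
            try:
                report: dict = {
                    "seed": config.seed,
                    "config_digest": config.digest(),
                    "kynet_version": __version__,
                    "threshold": results.get("threshold"),
                    "networks": {
                        g: {
                            "n_nodes": s.n_nodes,
                            "n_edges": s.n_edges,
                            "median_degree": s.median_degree,
                            "avg_clustering": s.avg_clustering,
                            "hubs": [list(h) for h in s.hubs],
                        }
                        for g, s in results["summaries"].items()
                    },
                }
                net_groups = list(results["summaries"])
                if len(net_groups) >= 2:
                    ga, gb = net_groups[0], net_groups[1]
                    perm = permutation_edge_test(
                        cohort[ga], cohort[gb], results["threshold"],
                        n_permutations=config.n_permutations, seed=config.seed)
                    d_stat, ks_p = ks_degree_test(
                        results["summaries"][ga], results["summaries"][gb])
                    diff_res = compare_groups(cohort[ga], cohort[gb], welch=config.welch)
                    differential = list(
                        diff_res.table.index[
                            diff_res.table["p_corrected"] <= config.differential_alpha]
                    )
                    overlap = hub_overlap(
                        results["summaries"][ga].hubs,
                        results["summaries"][gb].hubs,
                        differential)
                    report["edge_permutation"] = {
                        "observed_diff": perm.observed,
                        "p_value": perm.p_value,
                        "alternative": perm.alternative,
                        "n_permutations": perm.n_permutations,
                    }
                    report["ks_degree"] = {"D": d_stat, "p_value": ks_p}
                    report["differential_markers"] = differential
                    report["hub_overlap"] = {
                        k: sorted(v) for k, v in vars(overlap).items()}
                    results["comparison_report"] = report
            except (ParameterError, FormatError) as exc:
                raise StageError("compare", str(exc))

        caught.extend(f"{w.category.__name__}: {w.message}" for w in wrec)

    report["warnings"] = sorted(set(caught))
    with open(outdir / "comparison_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(outdir / "provenance.txt", "w") as fh:
        fh.write(f"kynet {__version__}\nseed {config.seed}\nconfig {config.digest()}\n")
        for line in yaml.safe_dump(config.analysis_dict(), sort_keys=True).splitlines():
            fh.write(f"  {line}\n")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.analysis_dict(), fh, sort_keys=True)
    results["report"] = report
    return results
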