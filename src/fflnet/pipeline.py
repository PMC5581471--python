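"""End-to-end orchestration: edges → FFLs → networks → expression filter →
significant FFLs → hubs → survival, with a machine-readable run report.

A run is driven by one :class:`RunConfig` naming either real input files
(edge lists, expression matrices, clinical table, node rosters) or a
:class:`~fflnet.synth.SimulationConfig`; every stage writes its output
under one run directory and contributes its cardinalities to a JSON
report mirroring the counts a study of this design tabulates (FFLs per
category, edges per type, nodes per class, significant FFLs, hubs,
per-component survival p).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import exprfilter, hubs as hubs_mod, network as network_mod, survival as survival_mod
from .ffl import FFLCategory, enumerate_ffls, ffl_summary, write_ffl_table
from .io import (
    EdgeType,
    NodeClass,
    NodeRoster,
    prefilter_edges,
    read_clinical_table,
    read_edge_list,
    read_expression_matrix,
    write_network,
)
from .synth import SimulationConfig, simulate_study, write_study

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """One pipeline run: exactly one of (input paths, simulation config)."""

    outdir: Path
    simulation: SimulationConfig | None = None
    # real-data inputs (all required together when simulation is None)
    edge_paths: Mapping[EdgeType, Path] | None = None
    mrna_path: Path | None = None
    mirna_path: Path | None = None
    clinical_path: Path | None = None
    genes_path: Path | None = None
    mirnas_path: Path | None = None
    tfs_path: Path | None = None
    # stage parameters
    prefilter_thresholds: dict[str, float] | None = None
    policy: exprfilter.ThresholdPolicy = field(default_factory=exprfilter.ThresholdPolicy)
    hub_method: str = "top_fraction"
    hub_fraction: float = 0.20
    hub_manual: dict[NodeClass, int] | None = None
    survival_percentiles: tuple[int, int] = (10, 90)
    survival_min_group_frac: float = 0.10
    survival_all_nodes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        have_real = self.edge_paths is not None
        if have_real == (self.simulation is not None):
            raise ValueError("provide exactly one of edge_paths or simulation")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs: dict = {"outdir": Path(raw["outdir"])}
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            if "planted" in sim:
                sim["planted"] = {FFLCategory(k): v for k, v in sim["planted"].items()}
            if "decoys" in sim:
                sim["decoys"] = {EdgeType(k): v for k, v in sim["decoys"].items()}
            if "true_r" in sim:
                sim["true_r"] = {EdgeType(k): v for k, v in sim["true_r"].items()}
            kwargs["simulation"] = SimulationConfig(**sim)
        if "edge_paths" in raw:
            kwargs["edge_paths"] = {EdgeType(k): Path(v) for k, v in raw["edge_paths"].items()}
        for key in ("mrna_path", "mirna_path", "clinical_path", "genes_path", "mirnas_path", "tfs_path"):
            if key in raw:
                kwargs[key] = Path(raw[key])
        for key in (
            "prefilter_thresholds",
            "hub_method",
            "hub_fraction",
            "survival_all_nodes",
            "survival_min_group_frac",
            "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "survival_percentiles" in raw:
            kwargs["survival_percentiles"] = tuple(raw["survival_percentiles"])
        if "hub_manual" in raw:
            kwargs["hub_manual"] = {NodeClass(k): v for k, v in raw["hub_manual"].items()}
        if "policy" in raw:
            pol = raw["policy"]
            rules = {
                EdgeType(k): exprfilter.EdgeRule(**v) for k, v in pol.get("rules", {}).items()
            }
            base = exprfilter.ThresholdPolicy(family=pol.get("family", "per_edge_type"))
            base.rules.update(rules)
            kwargs["policy"] = base
        return cls(**kwargs)


def _read_roster_file(path: Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        study = simulate_study(config.simulation, seed=config.seed)
        write_study(study, config.outdir / "inputs")
        return study.edges, study.mrna, study.mirna, study.clinical, study.truth.roster
    roster = NodeRoster(
        _read_roster_file(config.genes_path),
        _read_roster_file(config.mirnas_path),
        _read_roster_file(config.tfs_path),
    )
    edges = set()
    for etype, path in config.edge_paths.items():
        edges |= read_edge_list(path, etype, roster)
    mrna = read_expression_matrix(config.mrna_path, assay="MRNA")
    mirna = read_expression_matrix(config.mirna_path, assay="MIRNA")
    clinical = read_clinical_table(config.clinical_path)
    return edges, mrna, mirna, clinical, roster


def run(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    stage = "load"
    try:
        edges, mrna, mirna, clinical, roster = _load_inputs(config)
        report["input_edges_by_type"] = {
            t.value: sum(1 for e in edges if e.edge_type is t) for t in EdgeType
        }

        stage = "prefilter"
        if config.prefilter_thresholds:
            edges = prefilter_edges(edges, config.prefilter_thresholds)
        report["edges_after_prefilter"] = len(edges)
        logger.info("prefilter: %d edges retained", len(edges))

        stage = "enumerate_ffls"
        ffls = enumerate_ffls(edges)
        write_ffl_table(ffls, out / "ffls.tsv")
        summary = ffl_summary(ffls)
        summary.to_csv(out / "ffl_summary.tsv", sep="\t")
        report["ffls_by_category"] = {
            c.value: int(summary.loc[c.value, "n_ffls"]) for c in FFLCategory
        }
        report["ffls_total"] = int(summary.loc["Total", "n_ffls"])
        logger.info("enumerated %d FFLs", report["ffls_total"])

        stage = "merge_networks"
        rosters_sizes = {
            NodeClass.GENE: len(roster.genes),
            NodeClass.MIRNA: len(roster.mirnas),
            NodeClass.TF: len(roster.tfs),
        }
        full = network_mod.merge_ffls(ffls)
        report["network"] = network_mod.network_summary(full, rosters_sizes)
        report["subnetworks"] = {}
        for cat in FFLCategory:
            snw = network_mod.merge_ffls(ffls, [cat])
            report["subnetworks"][cat.value] = network_mod.network_summary(snw, rosters_sizes)
            if snw.edges:
                write_network(snw, out / f"snw_{cat.value.lower()}.sif", "SIF")
                network_mod.degree_table(snw).to_csv(
                    out / f"degrees_{cat.value.lower()}.tsv", sep="\t", index=False
                )
        if full.edges:
            write_network(full, out / "network_full.sif", "SIF")
            write_network(full, out / "network_full.tsv", "TSV")
            write_network(full, out / "network_full.graphml", "GRAPHML")
            network_mod.degree_table(full).to_csv(out / "degrees_full.tsv", sep="\t", index=False)

        stage = "expression_filter"
        significant_ffls = []
        if full.edges:
            results = exprfilter.significant_pairs(full.edges, mrna, mirna, config.policy)
            exprfilter.results_to_frame(results).to_csv(
                out / "correlation_report.tsv", sep="\t", index=False
            )
            report["significant_edges_by_type"] = {
                t.value: sum(
                    1 for res in results if res.significant and res.edge.edge_type is t
                )
                for t in EdgeType
            }
            stage = "extract_significant_ffls"
            significant_ffls = exprfilter.extract_significant_ffls(ffls, results)
        write_ffl_table(significant_ffls, out / "significant_ffls.tsv")
        report["significant_ffls_by_category"] = {
            c.value: sum(1 for f in significant_ffls if f.category is c) for c in FFLCategory
        }
        report["significant_ffls_total"] = len(significant_ffls)
        logger.info("%d significant FFLs", len(significant_ffls))

        stage = "hubs"
        report["hubs"] = {}
        hub_components: list[str] = []
        sig_net = network_mod.merge_ffls(significant_ffls)
        if sig_net.edges:
            write_network(sig_net, out / "network_significant.sif", "SIF")
            deg = network_mod.degree_table(sig_net)
            deg.to_csv(out / "degrees_significant.tsv", sep="\t", index=False)
            cutoffs = hubs_mod.hub_cutoffs(
                deg,
                method=config.hub_method,
                fraction=config.hub_fraction,
                manual=config.hub_manual,
            )
            hub_report = hubs_mod.identify_hubs(deg, cutoffs)
            hub_report.hubs.to_csv(out / "hubs.tsv", sep="\t", index=False)
            report["hubs"] = {
                "cutoffs": {c.value: int(v) for c, v in cutoffs.items()},
                "nodes": hub_report.hubs.to_dict(orient="records"),
            }
            hub_components = hub_report.hub_nodes()

        stage = "survival"
        components = hub_components
        if config.survival_all_nodes:
            components = sorted(sig_net.nodes) if sig_net.edges else []
        report["survival"] = {}
        rows = []
        for comp in components:
            row = mirna.row(comp)
            if row is None:
                row = mrna.row(comp)
            if row is None or clinical.empty:
                continue
            try:
                cp = survival_mod.optimal_cutpoint(
                    row,
                    clinical,
                    component=comp,
                    percentiles=config.survival_percentiles,
                    min_group_frac=config.survival_min_group_frac,
                )
            except ValueError as exc:
                logger.warning("survival skipped for %s: %s", comp, exc)
                continue
            report["survival"][comp] = {
                "cutpoint": cp.cutpoint,
                "n_low": cp.n_low,
                "n_high": cp.n_high,
                "logrank_statistic": cp.statistic,
                "p": cp.p,
                "p_corrected": cp.p_corrected,
                "direction": cp.direction,
            }
            rows.append({"component": comp, **report["survival"][comp]})
        if rows:
            import pandas as pd

            pd.DataFrame(rows).to_csv(out / "survival_cutpoints.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
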