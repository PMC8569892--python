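"""End-to-end orchestration: preprocess -> networks (metacommunity,
sediment, water) -> topology -> null models -> modules/roles -> linkage.

Each stage writes its outputs to the run directory so stages are
independently inspectable and re-runnable; a manifest records the full
configuration, seeds and package versions needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io, linkage, modules, network, nullmodel, preprocess, topology

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, seeds and paths for one full analysis run.

    Defaults are the standard settings of this analysis: joint presence
    in >= 8 lakes, mean relative abundance > 0.01%, |Spearman R| > 0.80
    with BH-adjusted P < 0.01, 999 null replicates, major modules with
    more than 10 nodes, and role cuts Zi >= 2.5 / Pi >= 0.62.
    """

    otu_table: str = ""
    metadata: str = ""
    env_table: str = ""
    taxonomy: str | None = None
    outdir: str = "thermonet_run"
    rarefaction_depth: int | None = None
    min_lakes: int = 8
    min_ra: float = 1e-4
    r_min: float = 0.80
    alpha_edges: float = 0.01
    alpha_enrich: float = 0.05
    major_min_size: int = 11
    zi_cut: float = 2.5
    pi_cut: float = 0.62
    null_reps: int = 999
    null_metrics: tuple = topology.PANEL_METRICS
    detect_method: str = "greedy"
    p_method: str = "ols"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.r_min <= 1:
            raise ValueError("r_min must lie in [0, 1]")
        for a in (self.alpha_edges, self.alpha_enrich):
            if not 0 < a < 1:
                raise ValueError("alpha thresholds must lie in (0, 1)")
        if self.min_lakes < 1 or self.major_min_size < 1:
            raise ValueError("count thresholds must be positive")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["null_metrics"] = list(d["null_metrics"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "null_metrics" in d:
            d["null_metrics"] = tuple(d["null_metrics"])
        return cls(**d)


def _analyze_network(name: str, G: nx.Graph, cfg: PipelineConfig,
                     outdir: Path, node_attrs: pd.DataFrame | None,
                     run_nulls: bool = True) -> dict:
    report: dict = {"network": name, "n_nodes": G.number_of_nodes(),
                    "n_edges": G.number_of_edges()}
    network.edge_table(G).to_csv(outdir / f"{name}_edges.tsv", sep="\t", index=False)
    if G.number_of_nodes() == 0:
        logger.warning("network %r has no edges at |R| > %.2f; "
                       "downstream stages skipped", name, cfg.r_min)
        report["skipped"] = "empty network"
        return report
    part = modules.detect_modules(G, method=cfg.detect_method, seed=cfg.seed)
    roles = modules.node_role_table(G, part, zi_cut=cfg.zi_cut, pi_cut=cfg.pi_cut)
    majors = modules.major_modules(part, min_size=cfg.major_min_size)
    summary = topology.network_summary(G, partition=part)
    node_df = roles.copy()
    if node_attrs is not None:
        node_df = node_df.join(node_attrs, how="left")
    node_df.to_csv(outdir / f"{name}_nodes.tsv", sep="\t")
    io.write_graphml(G, outdir / f"{name}.graphml", node_attrs=node_df)
    io.write_json(summary.to_dict(), outdir / f"{name}_topology.json")
    report.update(summary.to_dict())
    report["modularity_q"] = part.q
    report["n_modules"] = len(part.modules())
    report["major_modules"] = majors
    report["keystones"] = {
        role: int((roles["role"] == role).sum())
        for role in ("module hub", "connector", "network hub")
    }
    if run_nulls:
        null = nullmodel.null_ensemble(
            G.number_of_nodes(), G.number_of_edges(), reps=cfg.null_reps,
            seed=cfg.seed, metrics=cfg.null_metrics,
            detect_method=cfg.detect_method)
        comp = nullmodel.compare_to_null(summary, null)
        comp.to_csv(outdir / f"{name}_null_comparison.tsv", sep="\t")
        nullmodel.null_report(comp).to_csv(
            outdir / f"{name}_null_report.tsv", sep="\t")
        report["null"] = comp.to_dict(orient="index")
    return report, part, majors


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report dict (also written as
    JSON to the output directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = io.read_metadata(config.metadata)
    table = io.read_otu_table(config.otu_table, meta)
    env = io.read_env_table(config.env_table, meta)
    return run_pipeline_frames(table, env, config)


def run_pipeline_frames(table: preprocess.OTUTable, env: pd.DataFrame,
                        config: PipelineConfig) -> dict:
    """Same as :func:`run_pipeline` but starting from in-memory objects."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {**asdict(cfg), "null_metrics": list(cfg.null_metrics)},
                    "versions": {"thermonet": __version__,
                                 "numpy": np.__version__,
                                 "pandas": pd.__version__,
                                 "networkx": nx.__version__},
                    "started": datetime.datetime.now().isoformat(timespec="seconds")}

    if cfg.rarefaction_depth:
        table = preprocess.rarefy(table, cfg.rarefaction_depth, seed=cfg.seed)
    ra = preprocess.relative_abundance(table)

    enrich = preprocess.classify_enrichment(ra, alpha=cfg.alpha_enrich)
    enrich.table.to_csv(outdir / "enrichment.tsv", sep="\t")
    report["enrichment_counts"] = enrich.counts().to_dict()
    node_attrs = enrich.table[["label"]].rename(columns={"label": "enrichment"})

    meta_otus = preprocess.filter_metacommunity(
        ra, min_lakes=cfg.min_lakes, min_ra=cfg.min_ra)
    (outdir / "metacommunity_otus.txt").write_text("\n".join(meta_otus) + "\n")

    networks: dict[str, nx.Graph] = {}
    networks["metacommunity"] = network.correlation_network(
        ra, otu_set=meta_otus, r_min=cfg.r_min, alpha=cfg.alpha_edges)
    for hab in ("sediment", "water"):
        otus = preprocess.filter_habitat(
            ra, hab, min_lakes=cfg.min_lakes, min_mean_ra=cfg.min_ra)
        (outdir / f"{hab}_otus.txt").write_text("\n".join(otus) + "\n")
        networks[hab] = network.correlation_network(
            ra, otu_set=otus, samples=ra.samples_of(hab),
            r_min=cfg.r_min, alpha=cfg.alpha_edges)

    report["networks"] = {}
    partitions: dict[str, modules.ModulePartition] = {}
    majors: dict[str, list] = {}
    for name, G in networks.items():
        result = _analyze_network(name, G, cfg, outdir, node_attrs)
        if isinstance(result, tuple):
            rep, part, maj = result
            partitions[name] = part
            majors[name] = maj
        else:
            rep = result
        report["networks"][name] = rep

    # env -> module -> community path models, per habitat
    report["path_models"] = {}
    for hab in ("sediment", "water"):
        if hab not in partitions or not majors.get(hab):
            logger.warning("no major modules for %s; path model skipped", hab)
            continue
        samples = list(ra.samples_of(hab))
        part = partitions[hab]
        env_hab = env.loc[samples]
        env_dists = {v: linkage.env_distance(env_hab, v, samples=samples)
                     for v in env_hab.columns
                     if env_hab[v].notna().all() and env_hab[v].nunique() > 1}
        module_betas = {
            mod: linkage.bray_curtis(ra, otu_subset=part.nodes_of(mod),
                                     samples=samples)
            for mod in majors[hab]
        }
        community = linkage.bray_curtis(ra, samples=samples)
        fit = linkage.fit_path_model(env_dists, module_betas, community,
                                     p_method=cfg.p_method, seed=cfg.seed)
        fit.paths.to_csv(outdir / f"{hab}_path_model.tsv", sep="\t", index=False)
        contrib = linkage.module_contribution_summary(fit)
        contrib.to_csv(outdir / f"{hab}_module_contributions.tsv", sep="\t",
                       index=False)
        report["path_models"][hab] = {"r2": fit.r2,
                                      "n_pairs": fit.n_pairs,
                                      "p_method": fit.p_method}

    report["finished"] = datetime.datetime.now().isoformat(timespec="seconds")
    io.write_json(report, outdir / "report.json")
    cfg.to_yaml(outdir / "manifest.yaml")
    return report
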