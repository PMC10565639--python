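"""End-to-end orchestration: simulate -> QC -> cluster -> DE -> GSEA -> TCR.

Muscle and blood are clustered as separate analyses sharing one config.
Each stage reads its inputs from, and writes its outputs to, the run
directory, so any stage can be rerun from cached upstream outputs and
reproduce the full-run files bit for bit.  All randomness flows from named
seeds in the config.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import de as de_mod
from . import gsea as gsea_mod
from . import io
from . import qc as qc_mod
from . import simulate as sim
from . import tcr as tcr_mod
from .config import ConfigError, DEConfig, QCThresholds, SimConfig, _from_dict

STAGES = ["simulate", "qc", "cluster", "de", "gsea", "tcr"]
# treatment labels marking the collagenase-digestion experiment arms
DIGESTION_TREATMENTS = ("collagenase", "untreated")


@dataclass
class ClusterParams:
    pcs: int = 8
    knn: int = 20
    resolution: float = 1.0
    seed: int = 7
    batch_adjust: str = "center"

    def __post_init__(self) -> None:
        if self.batch_adjust not in ("center", "none"):
            raise ConfigError("batch_adjust must be 'center' or 'none'")
        if self.pcs < 1 or self.knn < 1:
            raise ConfigError("pcs and knn must be positive")


@dataclass
class GseaParams:
    gmt: str | None = None
    target_clusters: list[int] | str = "auto"
    rest_clusters: list[int] | str = "auto"
    n_perm: int = 1000
    seed: int = 7
    weight: float = 1.0
    compartment: str = "muscle"


@dataclass
class TcrParams:
    match_mode: str = "strict"
    include_singletons: bool = False

    def __post_init__(self) -> None:
        if self.match_mode not in ("strict", "relaxed"):
            raise ConfigError("match_mode must be 'strict' or 'relaxed'")


@dataclass
class RunConfig:
    outdir: str = "run"
    simulate: SimConfig | None = None
    inputs: dict | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    gene_family_rules: list[str] | None = None
    clustering: dict[str, ClusterParams] = field(default_factory=dict)
    de: DEConfig = field(default_factory=DEConfig)
    gsea: GseaParams = field(default_factory=GseaParams)
    tcr: TcrParams | None = field(default_factory=TcrParams)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulate' or 'inputs' required")
        if not self.clustering:
            # muscle and blood elbow at different depths by convention
            self.clustering = {"muscle": ClusterParams(pcs=8),
                               "PB": ClusterParams(pcs=7)}
        if self.inputs is not None:
            for key in ("matrix", "genes", "barcodes", "meta"):
                if key not in self.inputs:
                    raise ConfigError(f"inputs block missing '{key}' path")
                if not Path(self.inputs[key]).exists():
                    raise ConfigError(f"input file not found: {self.inputs[key]}")
        if self.gsea.gmt is not None and not Path(self.gsea.gmt).exists():
            raise ConfigError(f"GMT file not found: {self.gsea.gmt}")


def validate_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
    if data.get("simulate") is not None:
        data["simulate"] = SimConfig.from_dict(data["simulate"])
    if data.get("qc") is not None:
        data["qc"] = QCThresholds.from_dict(data["qc"])
    if data.get("de") is not None:
        data["de"] = DEConfig.from_dict(data["de"])
    if data.get("gsea") is not None:
        data["gsea"] = _from_dict(GseaParams, data["gsea"])
    if "tcr" in data:
        data["tcr"] = (_from_dict(TcrParams, data["tcr"])
                       if data["tcr"] is not None else None)
    if data.get("clustering") is not None:
        data["clustering"] = {comp: _from_dict(ClusterParams, params)
                              for comp, params in data["clustering"].items()}
    return RunConfig(**data)


def _input_paths(cfg: RunConfig) -> dict:
    if cfg.simulate is not None:
        d = Path(cfg.outdir) / "input"
        paths = {"matrix": d / "matrix.mtx", "genes": d / "genes.tsv",
                 "barcodes": d / "barcodes.tsv", "meta": d / "cell_meta.tsv",
                 "counts": d / "counts.mtx", "airr": d / "tcr.airr.tsv",
                 "gmt": d / "trm_demo.gmt", "truth": d / "truth.json"}
        return {k: str(v) for k, v in paths.items()}
    return dict(cfg.inputs)


def _load_matrix(cfg: RunConfig, which: str):
    d = Path(cfg.outdir)
    if which == "input":
        p = _input_paths(cfg)
        counts = p.get("counts")
        if counts is not None and not Path(counts).exists():
            counts = None
        return io.read_expression_matrix(p["matrix"], p["genes"],
                                         p["barcodes"], p["meta"],
                                         counts_path=counts)
    sub = d / which
    counts = sub / "counts.mtx"
    return io.read_expression_matrix(
        sub / "matrix.mtx", sub / "genes.tsv", sub / "barcodes.tsv",
        sub / "cell_meta.tsv",
        counts_path=counts if counts.exists() else None)


def _load_truth(cfg: RunConfig) -> sim.GroundTruth | None:
    p = _input_paths(cfg).get("truth")
    if p and Path(p).exists():
        with open(p) as fh:
            return sim.GroundTruth.from_dict(json.load(fh))
    return None


def _is_digestion_arm(meta: pd.DataFrame) -> pd.Series:
    return meta["treatment"].isin(DIGESTION_TREATMENTS)


def stage_simulate(cfg: RunConfig) -> dict:
    if cfg.simulate is None:
        return {"skipped": "inputs supplied externally"}
    paths = sim.simulate_cohort(cfg.simulate, Path(cfg.outdir) / "input")
    return {"files": paths}


def stage_qc(cfg: RunConfig) -> dict:
    m = _load_matrix(cfg, "input")
    filtered, report = qc_mod.apply_cell_filters(m, cfg.qc)
    clean = qc_mod.drop_gene_families(filtered, cfg.gene_family_rules)
    outdir = Path(cfg.outdir)
    report.cells.reset_index().to_csv(outdir / "qc_report.tsv", sep="\t",
                                      index=False)
    io.write_json({"stage_counts": report.stage_counts,
                   "warnings": report.warnings,
                   "genes_after_family_removal": clean.n_genes},
                  outdir / "qc_summary.json")
    io.write_expression_matrix(clean, outdir / "clean")
    return {"cells_in": m.n_cells, "cells_pass": filtered.n_cells,
            "genes_in": m.n_genes, "genes_after_family_removal": clean.n_genes}


def stage_cluster(cfg: RunConfig) -> dict:
    m = _load_matrix(cfg, "clean")
    nm = cl.normalize_cp10k_log(m)
    patient_cells = ~_is_digestion_arm(nm.cell_meta)
    info: dict = {}
    cluster_rows = []
    comp_tables = []
    outdir = Path(cfg.outdir)
    for comp, params in cfg.clustering.items():
        mask = (patient_cells & (nm.cell_meta["compartment"] == comp)).to_numpy()
        if mask.sum() == 0:
            warnings.warn(f"no cells in compartment {comp!r}; skipped")
            continue
        sub = nm.subset_cells(mask)
        emb = cl.pca_embed(sub, k=params.pcs)
        if params.batch_adjust == "center":
            emb = cl.adjust_batch(emb, sub.cell_meta["batch"])
        ca = cl.knn_louvain(emb, k_neighbors=params.knn,
                            resolution=params.resolution, seed=params.seed)
        lineage = cl.assign_lineage(sub)
        comp_df = pd.DataFrame({
            "cell_id": list(sub.cell_ids),
            "compartment": comp,
            "cluster": ca.labels.to_numpy(),
            "lineage": lineage.to_numpy(),
        })
        cluster_rows.append(comp_df)
        comp_tab = cl.cluster_composition(ca, sub.cell_meta)
        comp_tab.insert(0, "compartment", comp)
        comp_tables.append(comp_tab)
        emb_df = pd.DataFrame(emb.coordinates,
                              columns=[f"PC{i + 1}" for i in range(emb.k)])
        emb_df.insert(0, "cell_id", list(sub.cell_ids))
        emb_df.to_csv(outdir / f"embedding_{comp}.tsv", sep="\t", index=False)
        info[comp] = {"n_cells": int(mask.sum()),
                      "n_clusters": ca.n_clusters,
                      "modularity": ca.modularity,
                      "params": dataclasses.asdict(params)}
    pd.concat(cluster_rows, ignore_index=True).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False)
    pd.concat(comp_tables, ignore_index=True).to_csv(
        outdir / "composition.tsv", sep="\t", index=False)
    return info


def _read_clusters(cfg: RunConfig) -> pd.DataFrame:
    return pd.read_csv(Path(cfg.outdir) / "clusters.tsv", sep="\t")


def stage_de(cfg: RunConfig) -> dict:
    m = _load_matrix(cfg, "clean")
    nm = cl.normalize_cp10k_log(m)
    clusters = _read_clusters(cfg)
    outdir = Path(cfg.outdir)
    info: dict = {}

    marker_tables = []
    for comp in cfg.clustering:
        sub_clusters = clusters[clusters["compartment"] == comp]
        if sub_clusters.empty or sub_clusters["cluster"].nunique() < 2:
            continue
        mask = np.isin(np.asarray(nm.cell_ids, dtype=object),
                       sub_clusters["cell_id"].to_numpy())
        sub = nm.subset_cells(mask)
        labels = sub_clusters.set_index("cell_id")["cluster"]
        markers = de_mod.find_all_markers(sub, labels, cfg.de)
        markers.insert(0, "compartment", comp)
        marker_tables.append(markers)
        info[f"markers_{comp}"] = int(len(markers))
    markers_all = (pd.concat(marker_tables, ignore_index=True)
                   if marker_tables else pd.DataFrame())
    markers_all.to_csv(outdir / "markers.tsv", sep="\t", index=False)

    dig_mask = _is_digestion_arm(nm.cell_meta)
    if dig_mask.any():
        dig = nm.subset_cells(dig_mask.to_numpy())
        treated = (dig.cell_meta["treatment"] == "collagenase").to_numpy()
        blocklist = de_mod.digestion_blocklist(dig, treated, cfg.de)
    else:
        blocklist = pd.DataFrame(columns=["gene", "log2fc", "p_value",
                                          "p_adjusted", "direction"])
        warnings.warn("no digestion arms in metadata; blocklist is empty")
    blocklist.to_csv(outdir / "blocklist.tsv", sep="\t", index=False)
    info["blocklist_genes"] = int(len(blocklist))

    patients = nm.subset_cells((~dig_mask).to_numpy())
    comp_labels = patients.cell_meta["compartment"]
    if comp_labels.nunique() >= 2:
        tissue_table, top50 = de_mod.tissue_vs_blood_de(
            patients, comp_labels, blocklist, cfg.de)
        tissue_table.to_csv(outdir / "tissue_markers.tsv", sep="\t",
                            index=False)
        top50.to_csv(outdir / "top50_up.tsv", sep="\t", index=False)
        info["tissue_de_genes"] = int(len(tissue_table))
        info["top50"] = int(len(top50))
    return info


def _auto_gsea_targets(cfg: RunConfig, clusters: pd.DataFrame,
                       comp: str) -> tuple[list[int], list[int]]:
    """Map discovered clusters to planted ones (majority vote) and target
    the clusters dominated by the planted expansion-biased modules."""
    truth = _load_truth(cfg)
    if truth is None:
        raise ConfigError("gsea target_clusters='auto' needs a ground-truth "
                          "file; specify explicit cluster ids instead")
    sub = clusters[clusters["compartment"] == comp]
    planted_targets = set(sim.TRM_CLUSTERS)
    votes = {}
    for c, grp in sub.groupby("cluster"):
        planted = [truth.cell_cluster.get(cell) for cell in grp["cell_id"]]
        votes[c] = pd.Series(planted).mode().iloc[0]
    target = sorted(c for c, p in votes.items() if p in planted_targets)
    rest = sorted(c for c in votes if c not in target)
    if not target or not rest:
        raise ConfigError("auto GSEA target selection found no split")
    return target, rest


def stage_gsea(cfg: RunConfig) -> dict:
    m = _load_matrix(cfg, "clean")
    nm = cl.normalize_cp10k_log(m)
    clusters = _read_clusters(cfg)
    comp = cfg.gsea.compartment
    gmt_path = cfg.gsea.gmt or _input_paths(cfg).get("gmt")
    if gmt_path is None or not Path(gmt_path).exists():
        raise ConfigError("no GMT file available for GSEA")
    gene_sets = io.read_gmt(gmt_path)
    if cfg.gsea.target_clusters == "auto":
        target, rest = _auto_gsea_targets(cfg, clusters, comp)
    else:
        target = list(cfg.gsea.target_clusters)
        rest = (list(cfg.gsea.rest_clusters)
                if cfg.gsea.rest_clusters != "auto" else
                sorted(set(clusters.loc[clusters["compartment"] == comp,
                                        "cluster"]) - set(target)))
    sub_clusters = clusters[clusters["compartment"] == comp]
    mask = np.isin(np.asarray(nm.cell_ids, dtype=object),
                   sub_clusters["cell_id"].to_numpy())
    sub = nm.subset_cells(mask)
    labels = sub_clusters.set_index("cell_id")["cluster"]
    ranked = gsea_mod.rank_genes(sub, labels, target, rest, cfg.de)
    table, results = gsea_mod.gsea_table(ranked, gene_sets,
                                         n_perm=cfg.gsea.n_perm,
                                         seed=cfg.gsea.seed,
                                         weight=cfg.gsea.weight)
    outdir = Path(cfg.outdir)
    table.to_csv(outdir / "gsea_results.tsv", sep="\t", index=False)
    ranked.to_csv(outdir / "gsea_ranking.tsv", sep="\t", index=False)
    for name, res in results.items():
        pd.DataFrame({"rank": np.arange(1, len(res.running_sum) + 1),
                      "running_sum": res.running_sum}).to_csv(
            outdir / f"gsea_trace_{name}.tsv", sep="\t", index=False)
    return {"target_clusters": target, "rest_clusters": rest,
            "gene_sets": list(gene_sets)}


def stage_tcr(cfg: RunConfig) -> dict:
    if cfg.tcr is None:
        return {"skipped": "no tcr block in config"}
    airr_path = _input_paths(cfg).get("airr")
    if airr_path is None or not Path(airr_path).exists():
        warnings.warn("no AIRR file available; TCR stage skipped")
        return {"skipped": "no AIRR input"}
    chains = io.read_airr_rearrangements(airr_path)
    clean = _load_matrix(cfg, "clean")
    # restrict to QC-passed cells
    chains = chains[chains["cell_id"].isin(set(clean.cell_ids))]
    receptors = tcr_mod.flag_tcr_doublets(chains)
    clusters = _read_clusters(cfg)
    cluster_label = pd.Series(
        (clusters["compartment"] + "_" + clusters["cluster"].astype(str)).values,
        index=clusters["cell_id"], name="cluster")
    nm = cl.normalize_cp10k_log(clean)
    lineage = cl.assign_lineage(nm)
    clones = tcr_mod.call_clonotypes(receptors, clean.cell_meta,
                                     clusters=cluster_label, lineage=lineage,
                                     match_mode=cfg.tcr.match_mode)
    outdir = Path(cfg.outdir)
    clones.reset_index().to_csv(outdir / "clonotypes.tsv", sep="\t",
                                index=False)
    expansion = tcr_mod.expansion_summary(clones)
    expansion.to_csv(outdir / "expansion.tsv", sep="\t", index=False)
    sharing = tcr_mod.clone_sharing(clones, axis="compartment")
    sharing.to_csv(outdir / "sharing.tsv", sep="\t", index=False)
    publicity = tcr_mod.clone_sharing(clones, axis="patient")
    publicity.to_csv(outdir / "publicity.tsv", sep="\t", index=False)
    n_public = int(publicity["public"].sum())
    if n_public:
        warnings.warn(f"PUBLIC CLONES DETECTED: {n_public} clone keys occur "
                      "in >= 2 patients")
    persistence = tcr_mod.clone_persistence(clones)
    persistence.to_csv(outdir / "persistence.tsv", sep="\t", index=False)
    net = tcr_mod.build_clone_network(
        clones, include_singletons=cfg.tcr.include_singletons)
    import networkx as nx
    nx.write_graphml(net, outdir / "clone_network.graphml")
    tcr_mod.network_edge_list(net).to_csv(outdir / "clone_network_edges.tsv",
                                          sep="\t", index=False)
    cov = tcr_mod.coverage_report(receptors)
    cov.update({"clonotypes": int(clones["clone_id"].nunique()),
                "expanded_clonotypes":
                    int(clones.loc[clones["expanded"], "clone_id"].nunique()),
                "public_clones": n_public})
    return cov


STAGE_FUNCS = {"simulate": stage_simulate, "qc": stage_qc,
               "cluster": stage_cluster, "de": stage_de, "gsea": stage_gsea,
               "tcr": stage_tcr}


def run_stage(cfg: RunConfig, stage: str) -> dict:
    if stage not in STAGE_FUNCS:
        raise ConfigError(f"unknown stage {stage!r}")
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    return STAGE_FUNCS[stage](cfg)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order and write report.json; returns the report."""
    report: dict = {"stages": {}, "warnings": []}
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                result = run_stage(cfg, stage)
            report["warnings"] += [f"{stage}: {w.message}" for w in caught]
        except Exception as exc:
            report["stages"][stage] = {"error": str(exc)}
            io.write_json(report, Path(cfg.outdir) / "report.json")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        result["wall_time_s"] = round(time.perf_counter() - t0, 3)
        report["stages"][stage] = result
    io.write_json(report, Path(cfg.outdir) / "report.json")
    return report
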