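"""Synthetic patient cohort with planted ground truth.

Emulates a plate-sorted full-length scRNA-seq study of T cells from
inflamed muscle and paired peripheral blood (PB): cluster-structured
negative-binomial expression with marker programs and CD4/CD8 lineage
genes, per-plate batch shifts, digestion-responsive genes up-shifted in
enzymatically dissociated muscle cells, planted low-quality cells for each
QC gate, a small collagenase-treated vs untreated PB experiment for
deriving the digestion blocklist, and a clonal paired-chain TCR repertoire
with expansion biased to chosen clusters, cross-compartment sharing,
timepoint persistence and 2a2b doublet wells.

Every planted feature is recorded in :class:`GroundTruth` so downstream
stages can be checked for exact recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import ConfigError, SimConfig
from .containers import ExpressionMatrix

# QC gate(s) each planted offender class is expected to trip.
OFFENDER_EXPECTED_REASONS = {
    "low_genes": ("min_genes",),
    "high_mito": ("max_mito",),
    "non_t_contaminant": ("cd3_low", "contaminant"),
    "rbc": ("hba",),
}

CONTAMINANT_GENES = ["CD14", "CD19", "CD22", "CD300E"]
CD3_GENES = ["CD3E", "CD3D", "CD3G"]
HBA_GENES = ["HBA1", "HBA2"]
MT_GENES = [
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB", "MT-RNR1",
]
RIBO_GENES = [f"RPL{i}" for i in range(3, 18)] + [f"RPS{i}" for i in range(2, 12)]
TR_GENES = (
    [f"TRAV{i}" for i in range(1, 6)] + [f"TRBV{i}" for i in range(1, 6)]
    + ["TRGV1", "TRGV2", "TRDV1", "TRDV2"]
    + ["TRAJ1", "TRAJ2", "TRAJ3", "TRBJ1", "TRBJ2", "TRAC", "TRBC1"]
)
# first planted marker module reuses canonical tissue-residency genes
TRM_MARKER_NAMES = ["ZNF683", "CXCR6", "XCL1", "XCL2", "CD69", "ITGAE",
                    "CRTAM", "ITGA1"]
# clusters carrying the tissue-residency program; depleted from blood
TRM_CLUSTERS = (1, 2)
TRM_BLOOD_DEPLETION = 0.1
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GroundTruth:
    """Planted features of a synthetic cohort, keyed by cell / gene / clone."""

    cell_cluster: dict[str, int] = field(default_factory=dict)
    cell_offender_reason: dict[str, str | None] = field(default_factory=dict)
    marker_genes: dict[int, list[str]] = field(default_factory=dict)
    cluster_lineage: dict[int, str] = field(default_factory=dict)
    collagenase_genes: list[str] = field(default_factory=list)
    batch_genes: list[str] = field(default_factory=list)
    clone_membership: dict[str, str | None] = field(default_factory=dict)
    clone_attributes: dict[str, dict] = field(default_factory=dict)
    doublet_cells: set[str] = field(default_factory=set)
    qc_metrics: dict[str, dict] = field(default_factory=dict)

    def offender_cells(self) -> set[str]:
        return {c for c, r in self.cell_offender_reason.items() if r}

    def expected_fail_reasons(self, cell: str) -> tuple[str, ...]:
        reason = self.cell_offender_reason.get(cell)
        return OFFENDER_EXPECTED_REASONS.get(reason, ()) if reason else ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["doublet_cells"] = sorted(self.doublet_cells)
        d["marker_genes"] = {str(k): v for k, v in self.marker_genes.items()}
        d["cluster_lineage"] = {str(k): v for k, v in self.cluster_lineage.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            cell_cluster={k: int(v) for k, v in d["cell_cluster"].items()},
            cell_offender_reason=dict(d["cell_offender_reason"]),
            marker_genes={int(k): list(v) for k, v in d["marker_genes"].items()},
            cluster_lineage={int(k): v for k, v in d["cluster_lineage"].items()},
            collagenase_genes=list(d["collagenase_genes"]),
            batch_genes=list(d["batch_genes"]),
            clone_membership=dict(d["clone_membership"]),
            clone_attributes=dict(d["clone_attributes"]),
            doublet_cells=set(d["doublet_cells"]),
            qc_metrics=dict(d.get("qc_metrics", {})),
        )


def build_gene_universe(cfg: SimConfig) -> tuple[list[str], dict]:
    """Assemble the gene list: reserved families, planted modules, fillers."""
    markers: dict[int, list[str]] = {}
    for c in range(1, cfg.n_clusters + 1):
        names = []
        for i in range(cfg.markers_per_cluster):
            if c == 1 and i < len(TRM_MARKER_NAMES):
                names.append(TRM_MARKER_NAMES[i])
            else:
                names.append(f"MK{c}_{i + 1:02d}")
        markers[c] = names
    collagenase = ["CREM", "FOSL2", "CXCR4"] + [
        f"DIG{i:03d}" for i in range(4, cfg.n_collagenase_genes + 1)
    ]
    reserved = (
        CD3_GENES + ["CD4", "CD8A", "CD8B"] + CONTAMINANT_GENES + HBA_GENES
        + MT_GENES + RIBO_GENES + TR_GENES + collagenase
        + [g for mod in markers.values() for g in mod]
    )
    if len(set(reserved)) != len(reserved):
        raise ConfigError("reserved gene names collide; reduce module sizes")
    n_filler = cfg.n_genes - len(reserved)
    if n_filler < 50:
        raise ConfigError(
            f"n_genes={cfg.n_genes} too small to host {len(reserved)} reserved "
            "gene names plus filler genes (need >= reserved + 50)"
        )
    fillers = [f"G{i:04d}" for i in range(1, n_filler + 1)]
    genes = reserved + fillers
    layout = {
        "markers": markers,
        "collagenase": collagenase,
        "fillers": fillers,
    }
    return genes, layout


def _cell_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-cell metadata plus planted cluster and offender labels."""
    rows = []
    reasons = list(cfg.offender_rates)
    probs = np.array([cfg.offender_rates[r] for r in reasons])
    choices = reasons + [None]
    pchoice = np.append(probs, 1 - probs.sum())
    idx = 0
    for patient in cfg.patients:
        # uneven but moderate cluster composition per patient; the
        # tissue-residency clusters are depleted from blood
        base = rng.dirichlet(np.full(cfg.n_clusters, 5.0))
        blood = base.copy()
        for c in TRM_CLUSTERS:
            if c <= cfg.n_clusters:
                blood[c - 1] *= TRM_BLOOD_DEPLETION
        blood = blood / blood.sum()
        for tp in cfg.timepoints(patient):
            batch = f"{patient}_{tp}"
            treatment = "early" if tp == cfg.timepoints(patient)[0] else "post"
            for comp in cfg.compartments:
                props = base if comp == "muscle" else blood
                for _ in range(cfg.n_cells_per_sample):
                    idx += 1
                    cluster = int(rng.choice(cfg.n_clusters, p=props)) + 1
                    offender = choices[int(rng.choice(len(choices), p=pchoice))]
                    rows.append((f"cell{idx:05d}", patient, comp, tp, batch,
                                 treatment, cluster, offender))
    # collagenase-digestion experiment arms (healthy-donor PB)
    for arm in ("untreated", "collagenase"):
        for _ in range(cfg.n_digestion_cells_per_arm):
            idx += 1
            cluster = int(rng.choice(cfg.n_clusters)) + 1
            rows.append((f"cell{idx:05d}", "HD1", "PB", "T1", "HD1_T1", arm,
                         cluster, None))
    return pd.DataFrame(
        rows,
        columns=["cell_id", "patient", "compartment", "timepoint", "batch",
                 "treatment", "cluster", "offender"],
    ).set_index("cell_id")


def simulate_expression(cfg: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the genes x cells count matrix and its RPKM-like view.

    Counts are negative binomial around per-cell means that combine a
    baseline gene program, cluster marker up-shifts (2**marker_log2_effect),
    lineage genes, a per-cell mitochondrial fraction, plate batch shifts on
    a random 10% of filler genes, digestion-responsive genes up-shifted in
    muscle and collagenase-treated cells, and per-offender perturbations.
    The RPKM-like view scales counts by a per-gene length (drawn once) and
    the cell's library size.
    """
    rng = np.random.default_rng(cfg.seed)
    genes, layout = build_gene_universe(cfg)
    gene_arr = np.array(genes, dtype=object)
    gidx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    cells = _cell_table(cfg, rng)
    n_cells = len(cells)

    # baseline weights (relative expression propensities)
    w0 = np.ones(n_genes)
    w0[[gidx[g] for g in layout["fillers"]]] = rng.lognormal(0.0, 1.0,
                                                             len(layout["fillers"]))
    for g in CD3_GENES:
        w0[gidx[g]] = 30.0
    for g in RIBO_GENES:
        w0[gidx[g]] = 8.0
    for g in TR_GENES:
        w0[gidx[g]] = 2.0
    for g in CONTAMINANT_GENES + HBA_GENES:
        w0[gidx[g]] = 0.0
    for g in layout["collagenase"]:
        w0[gidx[g]] = 1.5
    for mod in layout["markers"].values():
        for g in mod:
            w0[gidx[g]] = 2.0
    mt_rows = np.array([gidx[g] for g in MT_GENES])
    mt_w = rng.lognormal(0.0, 0.5, len(mt_rows))
    w0[mt_rows] = 0.0  # mitochondrial share handled separately per cell

    W = np.tile(w0[:, None], (1, n_cells))
    cluster_of = cells["cluster"].to_numpy()

    lineage = {}
    for c in range(1, cfg.n_clusters + 1):
        lineage[c] = "CD8" if c % 2 == 1 else "CD4"
    cd4, cd8a, cd8b = gidx["CD4"], gidx["CD8A"], gidx["CD8B"]
    eff = 2.0 ** cfg.marker_log2_effect
    for c in range(1, cfg.n_clusters + 1):
        cols = np.flatnonzero(cluster_of == c)
        rows = np.array([gidx[g] for g in layout["markers"][c]])
        W[np.ix_(rows, cols)] *= eff
        if lineage[c] == "CD8":
            W[cd8a, cols] = 20.0
            W[cd8b, cols] = 15.0
            W[cd4, cols] = 0.2
        else:
            W[cd4, cols] = 20.0
            W[cd8a, cols] = 0.2
            W[cd8b, cols] = 0.2

    # digestion-responsive genes: up in dissociated muscle and treated arm
    dig_rows = np.array([gidx[g] for g in layout["collagenase"]])
    digested = ((cells["compartment"] == "muscle")
                | (cells["treatment"] == "collagenase")).to_numpy()
    W[np.ix_(dig_rows, np.flatnonzero(digested))] *= 2.0 ** cfg.collagenase_log2_effect

    # plate batch shifts on a random 10% of filler genes (log-space additive)
    n_batch_genes = max(1, int(0.1 * n_genes))
    batch_gene_rows = rng.choice(
        [gidx[g] for g in layout["fillers"]],
        size=min(n_batch_genes, len(layout["fillers"])), replace=False,
    )
    batches = cells["batch"].to_numpy()
    for b in pd.unique(batches):
        shift = rng.normal(0.0, cfg.batch_shift_sd, len(batch_gene_rows))
        cols = np.flatnonzero(batches == b)
        W[np.ix_(batch_gene_rows, cols)] *= np.exp(shift)[:, None]

    # offender perturbations
    offender = cells["offender"].to_numpy()
    a, b = cfg.mito_fraction_beta
    mito_frac = rng.beta(a, b, n_cells)
    nonmito_rows = np.setdiff1d(np.arange(n_genes), mt_rows)
    for j in np.flatnonzero(offender == "high_mito"):
        a2, b2 = cfg.mito_fraction_beta_offender
        mito_frac[j] = rng.beta(a2, b2)
    for j in np.flatnonzero(offender == "non_t_contaminant"):
        for g in CD3_GENES:
            W[gidx[g], j] = 0.0
        for g in CONTAMINANT_GENES:
            W[gidx[g], j] = 25.0
    for j in np.flatnonzero(offender == "low_genes"):
        keep_n = max(50, int(0.3 * len(nonmito_rows)))
        expressed = np.flatnonzero(W[:, j] > 0)
        expressed = np.setdiff1d(expressed, mt_rows)
        cd3_rows = np.array([gidx[g] for g in CD3_GENES])
        pool = np.setdiff1d(expressed, cd3_rows)
        keep = rng.choice(pool, size=min(keep_n - len(cd3_rows), len(pool)),
                          replace=False)
        mask = np.ones(n_genes, bool)
        mask[keep] = False
        mask[cd3_rows] = False
        W[mask, j] = 0.0
    for j in np.flatnonzero(offender == "rbc"):
        s = W[:, j].sum()
        for g in HBA_GENES:
            W[gidx[g], j] = 0.03 * s

    # per-cell means: split library between mitochondrial and nuclear genes
    lib_mu, lib_sigma = cfg.library_size_lognormal
    lib = rng.lognormal(lib_mu, lib_sigma, n_cells)
    colsum = W.sum(axis=0)
    mu = W * ((1.0 - mito_frac) * lib / colsum)[None, :]
    mu[mt_rows, :] = (mt_w / mt_w.sum())[:, None] * (mito_frac * lib)[None, :]

    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12)),
                                   size=mu.shape).astype(float)
    counts[mu <= 0] = 0.0

    gene_len_kb = np.clip(rng.lognormal(np.log(1.5), 0.5, n_genes), 0.2, None)
    total = counts.sum(axis=0)
    rpkm = counts / gene_len_kb[:, None] / np.maximum(total, 1.0)[None, :] * 1e6

    meta = cells[["patient", "compartment", "timepoint", "batch", "treatment"]]
    matrix = ExpressionMatrix(values=rpkm, counts=counts, gene_ids=gene_arr,
                              cell_ids=cells.index.to_numpy(dtype=object),
                              cell_meta=meta)
    truth = GroundTruth(
        cell_cluster={c: int(k) for c, k in cells["cluster"].items()},
        cell_offender_reason={c: (o if isinstance(o, str) else None)
                              for c, o in cells["offender"].items()},
        marker_genes=layout["markers"],
        cluster_lineage=lineage,
        collagenase_genes=list(layout["collagenase"]),
        batch_genes=[genes[i] for i in sorted(batch_gene_rows)],
    )
    truth.qc_metrics = {
        cell: {
            "n_genes_detected": int((counts[:, j] > 0).sum()),
            "n_molecules": float(total[j]),
            "mito_pct": float(100.0 * counts[mt_rows, j].sum() / total[j])
            if total[j] > 0 else 0.0,
        }
        for j, cell in enumerate(cells.index)
    }
    return matrix, truth


def _rand_cdr3(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        n = int(rng.integers(8, 17))
        body = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, n))
        s = f"C{body}F"
        if s not in used:
            used.add(s)
            return s


def simulate_tcr(cfg: SimConfig, truth: GroundTruth,
                 cell_meta: pd.DataFrame) -> tuple[pd.DataFrame, GroundTruth]:
    """Plant a clonal paired-chain repertoire over the clean patient cells.

    Each clean T cell receives one productive alpha and one productive beta
    CDR3; clone members share both exactly.  Expanded clones (size >= 2,
    truncated-geometric sizes) are drawn per patient until
    ``expanded_cell_fraction`` of eligible cells belong to one, preferring
    cells of the biased clusters; clones span both compartments with
    ``share_across_compartment_prob`` and both timepoints (where the patient
    has two) with ``persist_prob``.  Doublet wells get two alpha and two
    beta chains and are excluded from clone membership.  Offender cells and
    digestion-arm cells emit no chains (assembly fails on poor wells).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    used: set[str] = set()
    chains: list[tuple] = []
    clean = [
        c for c in cell_meta.index
        if truth.cell_offender_reason.get(c) is None
        and cell_meta.loc[c, "patient"] != "HD1"
    ]
    meta = cell_meta.loc[clean]

    def emit(cell, locus, junction, productive=True):
        v = f"{locus}V{int(rng.integers(1, 6))}"
        j = f"{locus}J{int(rng.integers(1, 4))}"
        chains.append((cell, locus, productive, junction, v, j))

    clone_counter = 0
    for patient in cfg.patients:
        pcells = meta.index[meta["patient"] == patient]
        if len(pcells) == 0:
            continue
        is_doublet = rng.random(len(pcells)) < cfg.tcr_doublet_rate
        doublets = set(pcells[is_doublet])
        truth.doublet_cells |= doublets
        pool = meta.loc[[c for c in pcells if c not in doublets]].copy()
        pool["w"] = [
            cfg.expanded_clone_cluster_bias.get(truth.cell_cluster[c], 1.0)
            for c in pool.index
        ]
        target = int(round(cfg.expanded_cell_fraction * len(pool)))
        if target > len(pool):
            raise ConfigError("requested more clone cells than cells available")
        tps = cfg.timepoints(patient)
        assigned = 0
        while assigned < target and len(pool) >= 2:
            size = 2 + int(min(rng.geometric(cfg.clone_size_geometric_p) - 1,
                               cfg.clone_size_max - 2))
            comps_avail = sorted(pool["compartment"].unique())
            if len(comps_avail) > 1 and rng.random() < cfg.share_across_compartment_prob:
                comps = comps_avail
            else:
                comps = [comps_avail[int(rng.integers(len(comps_avail)))]]
            tps_used = list(tps)
            if len(tps) > 1 and rng.random() >= cfg.persist_prob:
                tps_used = [tps[0]]
            cand = pool[pool["compartment"].isin(comps)
                        & pool["timepoint"].isin(tps_used)]
            combos = (cand.groupby(["compartment", "timepoint"], observed=True)
                      .size().index.tolist())
            if len(cand) < 2 or len(combos) == 0:
                comps = [comps_avail[0]]
                tps_used = [tps[0]]
                cand = pool[pool["compartment"].isin(comps)
                            & pool["timepoint"].isin(tps_used)]
                combos = (cand.groupby(["compartment", "timepoint"],
                                       observed=True).size().index.tolist())
                if len(cand) < 2:
                    break
            size = max(size, len(combos))
            size = min(size, len(cand))
            if size < 2:
                break
            members: list[str] = []
            remaining = cand
            for comp, tp in combos:
                sub = remaining[(remaining["compartment"] == comp)
                                & (remaining["timepoint"] == tp)]
                w = sub["w"].to_numpy()
                pick = sub.index[int(rng.choice(len(sub), p=w / w.sum()))]
                members.append(pick)
                remaining = remaining.drop(pick)
            extra = size - len(members)
            if extra > 0 and len(remaining) > 0:
                w = remaining["w"].to_numpy()
                picks = rng.choice(len(remaining), size=min(extra, len(remaining)),
                                   replace=False, p=w / w.sum())
                members.extend(remaining.index[sorted(picks)])
            clone_counter += 1
            cid = f"{patient}_CL{clone_counter:04d}"
            alpha = _rand_cdr3(rng, used)
            beta = _rand_cdr3(rng, used)
            for cell in members:
                truth.clone_membership[cell] = cid
                emit(cell, "TRA", alpha)
                emit(cell, "TRB", beta)
            truth.clone_attributes[cid] = {
                "patient": patient,
                "size": len(members),
                "compartments": sorted({meta.loc[c, "compartment"]
                                        for c in members}),
                "timepoints": sorted({meta.loc[c, "timepoint"] for c in members}),
                "alpha": alpha,
                "beta": beta,
            }
            pool = pool.drop(members)
            assigned += len(members)
        # remaining cells: unique singleton receptors
        for cell in pool.index:
            clone_counter += 1
            cid = f"{patient}_CL{clone_counter:04d}"
            alpha = _rand_cdr3(rng, used)
            beta = _rand_cdr3(rng, used)
            truth.clone_membership[cell] = cid
            truth.clone_attributes[cid] = {
                "patient": patient,
                "size": 1,
                "compartments": [meta.loc[cell, "compartment"]],
                "timepoints": [meta.loc[cell, "timepoint"]],
                "alpha": alpha,
                "beta": beta,
            }
            emit(cell, "TRA", alpha)
            emit(cell, "TRB", beta)
        for cell in sorted(doublets):
            truth.clone_membership[cell] = None
            for _ in range(2):
                emit(cell, "TRA", _rand_cdr3(rng, used))
                emit(cell, "TRB", _rand_cdr3(rng, used))
    # occasional nonproductive chains
    for cell in clean:
        if rng.random() < cfg.nonproductive_chain_rate:
            locus = "TRA" if rng.random() < 0.5 else "TRB"
            emit(cell, locus, _rand_cdr3(rng, used), productive=False)

    table = pd.DataFrame(
        chains,
        columns=["cell_id", "locus", "productive", "junction_aa", "v_call",
                 "j_call"],
    )
    return table, truth


def trm_demo_gene_sets(truth: GroundTruth,
                       trm_clusters: tuple[int, ...] = TRM_CLUSTERS) -> dict:
    """Gene sets aligned to the planted modules, for enrichment demos."""
    up = sorted({g for c in trm_clusters for g in truth.marker_genes[c]})
    down = sorted({g for c, mod in truth.marker_genes.items()
                   if c not in trm_clusters for g in mod})
    return {"synthetic_trm_up": up, "synthetic_non_trm": down}


def simulate_cohort(cfg: SimConfig, outdir) -> dict:
    """Generate the full file bundle the pipeline reads.

    Writes matrix.mtx / counts.mtx / genes.tsv / barcodes.tsv /
    cell_meta.tsv, tcr.airr.tsv, trm_demo.gmt and truth.json; returns the
    path mapping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_expression(cfg)
    chains, truth = simulate_tcr(cfg, truth, matrix.cell_meta)
    paths = io.write_expression_matrix(matrix, outdir)
    paths["airr"] = outdir / "tcr.airr.tsv"
    io.write_airr_rearrangements(chains, paths["airr"])
    paths["gmt"] = outdir / "trm_demo.gmt"
    io.write_gmt(trm_demo_gene_sets(truth), paths["gmt"])
    paths["truth"] = outdir / "truth.json"
    io.write_json(truth.to_dict(), paths["truth"])
    return {k: str(v) for k, v in paths.items()}
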