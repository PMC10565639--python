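"""Cell-filter cascade and gene-family removal.

The gates target plate-sorted T cells quantified in RPKM-like units with a
parallel raw-count view: windows on detected genes and total molecules, a
mitochondrial-content ceiling, a CD3 identity gate, exclusion of cells
expressing myeloid/B-cell contaminant markers or hemoglobin, then removal
of TCR-segment and ribosomal gene families before clustering.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

from .config import ConfigError, QCThresholds
from .containers import ExpressionMatrix, QCReport
from .simulate import CD3_GENES, CONTAMINANT_GENES, HBA_GENES

# evaluation order of the gates; fail_reasons are reported in this order
FILTER_ORDER = ["min_genes", "max_genes", "min_molecules", "max_molecules",
                "max_mito", "cd3_low", "contaminant", "hba"]

DEFAULT_FAMILY_RULES = [r"^TR[ABGD][VDJC]", r"^RPL", r"^RPS"]
MITO_FAMILY_RULE = r"^MT-"


def _gene_rows(m: ExpressionMatrix, names: list[str]) -> dict[str, int]:
    present = {}
    genes = set(m.gene_ids)
    for g in names:
        if g in genes:
            present[g] = m.gene_index(g)
    return present


def compute_qc_metrics(m: ExpressionMatrix) -> QCReport:
    """Per-cell QC metrics: detected genes, molecules, mito %, gate genes.

    Molecule totals come from the raw-count view when present; otherwise
    the RPKM-like view is summed with a logged unit warning.  Cells with a
    zero column total get mito_pct = 0 by definition.
    """
    warns: list[str] = []
    if m.counts is not None:
        count_view = m.counts
    else:
        count_view = m.values
        warns.append("no raw-count view; molecule totals are column sums of "
                     "the expression view (unit caveat)")
        warnings.warn(warns[-1])
    n_genes_detected = (m.values > 0).sum(axis=0)
    n_molecules = count_view.sum(axis=0)
    mt_mask = np.array([bool(re.match(MITO_FAMILY_RULE, g)) for g in m.gene_ids])
    if not mt_mask.any():
        warns.append("no MT- genes found; mito_pct set to 0 for all cells")
        warnings.warn(warns[-1])
        mito_pct = np.zeros(m.n_cells)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_pct = 100.0 * count_view[mt_mask].sum(axis=0) / n_molecules
        mito_pct = np.where(n_molecules > 0, mito_pct, 0.0)

    cd3_rows = _gene_rows(m, CD3_GENES)
    cd3_max = (np.max(m.values[list(cd3_rows.values())], axis=0)
               if cd3_rows else np.zeros(m.n_cells))
    cd3_min = (np.min(m.values[list(cd3_rows.values())], axis=0)
               if cd3_rows else np.zeros(m.n_cells))
    cont_rows = _gene_rows(m, CONTAMINANT_GENES)
    hba_rows = _gene_rows(m, HBA_GENES)

    cells = pd.DataFrame(
        {
            "n_genes_detected": n_genes_detected.astype(int),
            "n_molecules": n_molecules,
            "mito_pct": mito_pct,
            "cd3_max_rpkm": cd3_max,
            "cd3_min_rpkm": cd3_min,
        },
        index=pd.Index(m.cell_ids, name="cell_id"),
    )
    for g, row in cont_rows.items():
        cells[g] = m.values[row]
    for g, row in hba_rows.items():
        cells[g] = m.values[row]
    return QCReport(cells=cells, warnings=warns)


def apply_cell_filters(m: ExpressionMatrix,
                       t: QCThresholds | None = None) -> tuple[ExpressionMatrix,
                                                               QCReport]:
    """Apply the cell-filter cascade; returns survivors and the QC ledger.

    A cell fails if ANY gate trips; every tripped gate is recorded in
    fail_reasons (ordered as in FILTER_ORDER).  Gene order is preserved.
    The CD3 gate requires the configured combination of CD3E/CD3D/CD3G to
    reach cd3_min_rpkm ("max" mode: any subunit suffices).
    """
    t = t or QCThresholds()
    cd3_present = [g for g in CD3_GENES if g in set(m.gene_ids)]
    if not cd3_present:
        raise ConfigError("CD3E/CD3D/CD3G absent from gene list; "
                          "cannot gate T cells")
    report = compute_qc_metrics(m)
    cells = report.cells

    fails = {}
    fails["min_genes"] = cells["n_genes_detected"] < t.min_genes
    fails["max_genes"] = cells["n_genes_detected"] > t.max_genes
    fails["min_molecules"] = cells["n_molecules"] < t.min_molecules
    fails["max_molecules"] = cells["n_molecules"] > t.max_molecules
    fails["max_mito"] = cells["mito_pct"] > t.max_mito_pct
    cd3_stat = cells["cd3_max_rpkm"] if t.cd3_mode == "max" else cells["cd3_min_rpkm"]
    fails["cd3_low"] = cd3_stat < t.cd3_min_rpkm
    cont = [g for g in CONTAMINANT_GENES if g in cells.columns]
    if cont:
        fails["contaminant"] = (cells[cont] > t.contaminant_max_rpkm).any(axis=1)
        cells["contaminant_flags"] = [
            ",".join(g for g in cont if row[g] > t.contaminant_max_rpkm)
            for _, row in cells.iterrows()
        ]
    else:
        fails["contaminant"] = pd.Series(False, index=cells.index)
        cells["contaminant_flags"] = ""
    hba = [g for g in HBA_GENES if g in cells.columns]
    if hba:
        if t.hba_mode == "sum":
            hba_value = cells[hba].sum(axis=1)
            fails["hba"] = hba_value > t.hba_max
        else:
            hba_value = cells[hba].min(axis=1)
            fails["hba"] = (cells[hba] > t.hba_max).all(axis=1)
        cells["hba_value"] = hba_value
    else:
        fails["hba"] = pd.Series(False, index=cells.index)
        cells["hba_value"] = 0.0

    reasons = []
    for cell in cells.index:
        reasons.append(",".join(r for r in FILTER_ORDER if bool(fails[r][cell])))
    cells["fail_reasons"] = reasons
    cells["verdict"] = np.where(cells["fail_reasons"] == "", "pass", "fail")

    report.stage_counts = {r: int(fails[r].sum()) for r in FILTER_ORDER}
    report.stage_counts["pass"] = int((cells["verdict"] == "pass").sum())
    report.stage_counts["fail"] = int((cells["verdict"] == "fail").sum())
    report.stage_counts["input"] = int(len(cells))

    keep = (cells["verdict"] == "pass").to_numpy()
    return m.subset_cells(keep), report


def drop_gene_families(m: ExpressionMatrix,
                       families: list[str] | None = None) -> ExpressionMatrix:
    """Remove gene families matched by regex rules on the gene symbol.

    Defaults drop TCR segment genes (TRAV/TRBJ/TRAC, ...) so receptor usage
    cannot drive clustering, and cytosolic ribosomal RPL/RPS genes.  Cells
    are untouched.  Refuses to empty the matrix.
    """
    if families is None:
        families = list(DEFAULT_FAMILY_RULES)
    if not families:
        return m
    compiled = [re.compile(rule) for rule in families]
    drop = np.array([any(rx.match(g) for rx in compiled) for g in m.gene_ids])
    if drop.all():
        raise ValueError("gene-family rules would remove every gene")
    return m.subset_genes(~drop)
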