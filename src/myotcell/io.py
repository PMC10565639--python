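"""Readers and writers for the on-disk formats the pipeline consumes.

Expression matrices travel as MatrixMarket coordinate files (1-based
indices) with parallel ``genes.tsv`` / ``barcodes.tsv`` label files and a
``cell_meta.tsv`` metadata table, or as dense CSV with genes as rows.
TCR rearrangements travel as AIRR Rearrangement TSV; gene sets as GMT.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import META_COLUMNS, ExpressionMatrix

AIRR_REQUIRED_COLUMNS = ["cell_id", "locus", "productive", "junction_aa",
                         "v_call", "j_call"]


def _read_labels(path) -> np.ndarray:
    labels = pd.read_csv(path, sep="\t", header=None)[0].astype(str).to_numpy()
    return labels.astype(object)


def read_cell_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in meta.columns:
        raise ValueError(f"{path}: cell_meta must have a cell_id column")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: cell_meta missing columns {missing}")
    if meta["cell_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate cell_id in metadata")
    return meta.set_index("cell_id")


def read_expression_matrix(matrix_path, genes_path, cells_path, meta_path,
                           counts_path=None) -> ExpressionMatrix:
    """Read a MatrixMarket matrix plus gene/cell labels and cell metadata.

    ``counts_path`` optionally supplies a parallel raw-count matrix of the
    same shape (same gene/cell order) used for molecule-based QC metrics.
    """
    try:
        values = scipy.io.mmread(matrix_path)
    except Exception as exc:  # malformed header or body
        raise ValueError(f"{matrix_path}: malformed MatrixMarket file: {exc}")
    values = np.asarray(
        values.todense() if scipy.sparse.issparse(values) else values, dtype=float
    )
    genes = _read_labels(genes_path)
    cells = _read_labels(cells_path)
    if values.shape != (len(genes), len(cells)):
        raise ValueError(
            f"dimension mismatch: matrix is {values.shape} but "
            f"{genes_path} lists {len(genes)} genes and "
            f"{cells_path} lists {len(cells)} cells"
        )
    counts = None
    if counts_path is not None:
        counts = scipy.io.mmread(counts_path)
        counts = np.asarray(
            counts.todense() if scipy.sparse.issparse(counts) else counts,
            dtype=float,
        )
        if counts.shape != values.shape:
            raise ValueError("counts matrix shape differs from expression matrix")
    meta = read_cell_meta(meta_path)
    missing = set(cells) - set(meta.index)
    if missing:
        raise ValueError(f"metadata missing for cells: {sorted(missing)[:5]} ...")
    return ExpressionMatrix(values=values, counts=counts, gene_ids=genes,
                            cell_ids=cells, cell_meta=meta)


def read_expression_csv(values_csv, meta_path) -> ExpressionMatrix:
    """Read a dense CSV (genes as rows, cells as columns) plus metadata."""
    df = pd.read_csv(values_csv, index_col=0)
    meta = read_cell_meta(meta_path)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=df.index.to_numpy(dtype=object),
        cell_ids=df.columns.to_numpy(dtype=object),
        cell_meta=meta,
    )


def write_expression_matrix(m: ExpressionMatrix, outdir, prefix="") -> dict:
    """Write matrix.mtx + genes.tsv + barcodes.tsv + cell_meta.tsv.

    Returns the mapping of logical names to paths.  The raw-count view, if
    present, is written alongside as counts.mtx.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}matrix.mtx",
        "genes": outdir / f"{prefix}genes.tsv",
        "barcodes": outdir / f"{prefix}barcodes.tsv",
        "meta": outdir / f"{prefix}cell_meta.tsv",
    }
    scipy.io.mmwrite(
        paths["matrix"], scipy.sparse.coo_matrix(m.values), precision=17
    )
    pd.Series(m.gene_ids).to_csv(paths["genes"], sep="\t", index=False, header=False)
    pd.Series(m.cell_ids).to_csv(paths["barcodes"], sep="\t", index=False,
                                 header=False)
    m.cell_meta.reset_index(names="cell_id").to_csv(paths["meta"], sep="\t",
                                                    index=False)
    if m.counts is not None:
        paths["counts"] = outdir / f"{prefix}counts.mtx"
        scipy.io.mmwrite(
            paths["counts"], scipy.sparse.coo_matrix(m.counts), precision=17
        )
    return paths


def read_airr_rearrangements(path) -> pd.DataFrame:
    """Read an AIRR Rearrangement TSV into a typed chain table.

    Required columns: cell_id, locus, productive (T/F), junction_aa,
    v_call, j_call.  Extra columns are preserved.  TRG/TRD rows are kept
    but flagged so downstream paired-chain analysis can skip them.
    """
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in AIRR_REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required AIRR column(s): {missing}")
    table["productive"] = table["productive"].str.upper().isin(["T", "TRUE", "1"])
    bad = ~table["locus"].isin(["TRA", "TRB", "TRG", "TRD"])
    if bad.any():
        raise ValueError(
            f"{path}: unknown locus value(s): {sorted(table.loc[bad, 'locus'].unique())}"
        )
    empty = table["productive"] & (table["junction_aa"] == "")
    if empty.any():
        raise ValueError(f"{path}: productive rows with empty junction_aa")
    return table


def write_airr_rearrangements(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["productive"] = np.where(out["productive"].astype(bool), "T", "F")
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file: name, description, members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}: gene set {name!r} has no members")
            if len(set(genes)) != len(genes):
                raise ValueError(f"{path}: gene set {name!r} has duplicates")
            sets[name] = genes
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict[str, list[str]], path, description="synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
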