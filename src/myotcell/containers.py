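"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ["patient", "compartment", "timepoint", "batch", "treatment"]


@dataclass
class ExpressionMatrix:
    """Genes x cells expression matrix with per-cell metadata.

    ``values`` holds the primary (RPKM-like) view used for expression
    thresholds and normalization; ``counts`` optionally holds a parallel
    raw-count view used for molecule totals and mitochondrial fractions.
    Both are dense float arrays of shape (n_genes, n_cells).
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != self.values.shape:
                raise ValueError("counts view shape differs from values view")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("expression values must be finite and non-negative")
        missing = set(self.cell_ids) - set(self.cell_meta.index)
        if missing:
            raise ValueError(f"cell metadata missing for {len(missing)} cells")
        self.cell_meta = self.cell_meta.loc[list(self.cell_ids)]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(gene)
        return int(idx[0])

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return ExpressionMatrix(
            values=self.values[:, cols],
            counts=None if self.counts is None else self.counts[:, cols],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[cols],
            cell_meta=self.cell_meta.iloc[cols],
        )

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            rows = np.flatnonzero(mask)
        else:
            rows = mask
        return ExpressionMatrix(
            values=self.values[rows, :],
            counts=None if self.counts is None else self.counts[rows, :],
            gene_ids=self.gene_ids[rows],
            cell_ids=self.cell_ids,
            cell_meta=self.cell_meta,
        )


@dataclass
class NormalizedMatrix:
    """Genes x cells matrix after CP10k scaling and ln(1+x).

    For every cell, sum_g (exp(value) - 1) == 10,000 up to floating error.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    source: str = ""

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(np.asarray(self.gene_ids, dtype=object) == gene)
        if idx.size == 0:
            raise KeyError(gene)
        return int(idx[0])

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        cols = np.flatnonzero(mask) if mask.dtype == bool else mask
        return NormalizedMatrix(
            values=self.values[:, cols],
            gene_ids=self.gene_ids,
            cell_ids=np.asarray(self.cell_ids, dtype=object)[cols],
            cell_meta=self.cell_meta.iloc[cols],
            source=self.source,
        )

    def subset_genes(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        rows = np.flatnonzero(mask) if mask.dtype == bool else mask
        return NormalizedMatrix(
            values=self.values[rows, :],
            gene_ids=np.asarray(self.gene_ids, dtype=object)[rows],
            cell_ids=self.cell_ids,
            cell_meta=self.cell_meta,
            source=self.source,
        )


@dataclass
class PCEmbedding:
    """Cells x k principal-component coordinates."""

    coordinates: np.ndarray
    explained_variance: np.ndarray
    center: np.ndarray
    cell_ids: np.ndarray
    scale: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class ClusterAssignment:
    """Cell -> cluster labels (1..C) from graph community detection."""

    labels: pd.Series  # index cell_id, values int starting at 1
    modularity: float
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0


@dataclass
class QCReport:
    """Per-cell QC metrics, verdicts and failure reasons.

    ``cells`` has one row per input cell: n_genes_detected, n_molecules,
    mito_pct, cd3_max_rpkm, contaminant flags, hba_value, verdict and
    fail_reasons (comma-joined, ordered).  ``stage_counts`` counts cells
    failing each gate plus the passing cells.
    """

    cells: pd.DataFrame
    stage_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def n_pass(self) -> int:
        return int((self.cells["verdict"] == "pass").sum())

    @property
    def n_fail(self) -> int:
        return int((self.cells["verdict"] == "fail").sum())
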