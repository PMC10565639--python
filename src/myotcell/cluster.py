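"""Normalization, PCA embedding, batch centering, and kNN/Louvain clustering."""

from __future__ import annotations

import random
import warnings

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse
from sklearn.neighbors import NearestNeighbors

from .containers import (ClusterAssignment, ExpressionMatrix, NormalizedMatrix,
                         PCEmbedding)

LINEAGE_GENES = ("CD4", "CD8A", "CD8B")


def normalize_cp10k_log(m: ExpressionMatrix) -> NormalizedMatrix:
    """Scale each cell to 10,000 total, then ln(1+x).

    value = ln(1 + 10000 * x / colsum).  Afterwards every cell satisfies
    sum_g (exp(value) - 1) == 10,000 to relative 1e-6.
    """
    colsum = m.values.sum(axis=0)
    zero = np.flatnonzero(colsum <= 0)
    if zero.size:
        raise ValueError(
            f"cells with zero expression total cannot be normalized: "
            f"{list(m.cell_ids[zero[:5]])}"
        )
    values = np.log1p(m.values * (1e4 / colsum)[None, :])
    return NormalizedMatrix(values=values, gene_ids=m.gene_ids,
                            cell_ids=m.cell_ids, cell_meta=m.cell_meta,
                            source="cp10k_log")


def pca_embed(nm: NormalizedMatrix, k: int, scale: bool = True) -> PCEmbedding:
    """Project cells onto the top-k principal axes of the gene space.

    Genes are centered and (by default) scaled to unit variance; genes with
    zero variance are left at zero rather than divided out.  The sign of
    each axis is fixed by making its largest-magnitude gene loading
    positive, so embeddings are reproducible across runs and solvers.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = nm.values.T  # cells x genes
    n, g = X.shape
    if k > min(n, g):
        raise ValueError(f"k={k} exceeds matrix rank bound min(cells, genes)="
                         f"{min(n, g)}")
    center = X.mean(axis=0)
    Xc = X - center
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Xc = Xc / sd_safe
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size and S[0] > 0 else 0
    # sign convention: largest-|loading| entry of each axis is positive
    flip = np.ones(k)
    for i in range(min(k, rank)):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            flip[i] = -1.0
    S_eff = np.where(np.arange(k) < rank, S[:k], 0.0)
    coords = (U[:, :k] * S_eff) * flip[None, :]
    explained = (S_eff**2) / max(n - 1, 1)
    return PCEmbedding(coordinates=coords, explained_variance=explained,
                       center=center, scale=sd,
                       cell_ids=np.asarray(nm.cell_ids, dtype=object))


def adjust_batch(e: PCEmbedding, batches: pd.Series) -> PCEmbedding:
    """Shift each batch's mean in PC space onto the global mean.

    A deliberately simple, testable batch adjustment: per component, every
    batch with >= 2 cells is translated so its centroid coincides with the
    overall centroid.  Within-batch geometry is untouched; a single batch
    is the identity.  One-cell batches are left unshifted with a warning.
    """
    batches = batches.loc[list(e.cell_ids)]
    coords = e.coordinates.copy()
    labels = batches.to_numpy()
    uniq = pd.unique(labels)
    if len(uniq) > 1:
        global_mean = coords.mean(axis=0)
        for b in uniq:
            idx = np.flatnonzero(labels == b)
            if idx.size < 2:
                warnings.warn(f"batch {b!r} has a single cell; left unshifted")
                continue
            coords[idx] += global_mean - coords[idx].mean(axis=0)
    return PCEmbedding(coordinates=coords,
                       explained_variance=e.explained_variance,
                       center=e.center, scale=e.scale, cell_ids=e.cell_ids)


def snn_graph(coords: np.ndarray, k_neighbors: int = 20,
              prune: float = 1 / 15) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each cell is connected to its k nearest Euclidean neighbors (self
    included in the neighbor sets); edge weight is the Jaccard overlap of
    the two neighbor sets, pruned below ``prune``.
    """
    n = coords.shape[0]
    k = min(k_neighbors + 1, n)
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    idx = nn.kneighbors(coords, return_distance=False)
    rows = np.repeat(np.arange(n), k)
    A = scipy.sparse.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (A @ A.T).tocoo()
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    jaccard = s / (2 * k - s)
    keep = jaccard >= prune
    edges = list(zip(r[keep].tolist(), c[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jaccard[keep].tolist()
    return g


def louvain_partition(graph: ig.Graph, resolution: float = 1.0,
                      seed: int = 0) -> tuple[np.ndarray, float]:
    """Louvain modularity optimization on a weighted graph.

    Returns 1-based labels (relabelled by decreasing community size, ties
    by first occurrence) and the weighted modularity of the partition.
    Seeded for deterministic output.
    """
    rng = random.Random(seed)
    ig.set_random_number_generator(rng)
    try:
        weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
        part = graph.community_multilevel(weights=weights, resolution=resolution)
    finally:
        ig.set_random_number_generator(random)
    membership = np.asarray(part.membership)
    modularity = graph.modularity(membership, weights=weights)
    counts: dict[int, int] = {}
    first: dict[int, int] = {}
    for i, c in enumerate(membership.tolist()):
        counts[c] = counts.get(c, 0) + 1
        first.setdefault(c, i)
    order = sorted(counts, key=lambda c: (-counts[c], first[c]))
    relabel = {old: i + 1 for i, old in enumerate(order)}
    labels = np.array([relabel[c] for c in membership])
    return labels, float(modularity)


def knn_louvain(e: PCEmbedding, k_neighbors: int = 20, resolution: float = 1.0,
                seed: int = 0, prune: float = 1 / 15) -> ClusterAssignment:
    """Cluster cells on the SNN graph of their PC coordinates."""
    if k_neighbors >= e.coordinates.shape[0]:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    graph = snn_graph(e.coordinates, k_neighbors=k_neighbors, prune=prune)
    n_isolated = sum(1 for d in graph.degree() if d == 0)
    if n_isolated:
        warnings.warn(f"{n_isolated} cells are disconnected singletons")
    labels, modularity = louvain_partition(graph, resolution=resolution,
                                           seed=seed)
    series = pd.Series(labels, index=pd.Index(e.cell_ids, name="cell_id"),
                       name="cluster")
    return ClusterAssignment(labels=series, modularity=modularity,
                             params={"k_neighbors": k_neighbors,
                                     "resolution": resolution, "seed": seed,
                                     "prune": prune})


def cluster_composition(ca: ClusterAssignment,
                        meta: pd.DataFrame) -> pd.DataFrame:
    """Per (patient x cluster) cell counts and within-patient fractions."""
    df = pd.DataFrame({
        "patient": meta.loc[ca.labels.index, "patient"],
        "cluster": ca.labels,
    })
    counts = (df.groupby(["patient", "cluster"], observed=True).size()
              .rename("n_cells").reset_index())
    totals = counts.groupby("patient")["n_cells"].transform("sum")
    counts["fraction"] = counts["n_cells"] / totals
    return counts


def assign_lineage(nm: NormalizedMatrix) -> pd.Series:
    """Classify cells as CD4, CD8 or double-negative (DN) from expression.

    CD8 if max(CD8A, CD8B) exceeds CD4 and is positive; CD4 symmetrically;
    ties at positive values and all-zero cells are DN.
    """
    missing = [g for g in LINEAGE_GENES if g not in set(nm.gene_ids)]
    if missing:
        raise ValueError(f"lineage genes missing from matrix: {missing}")
    cd4 = nm.values[nm.gene_index("CD4")]
    cd8 = np.maximum(nm.values[nm.gene_index("CD8A")],
                     nm.values[nm.gene_index("CD8B")])
    lineage = np.where((cd8 > cd4) & (cd8 > 0), "CD8",
                       np.where((cd4 > cd8) & (cd4 > 0), "CD4", "DN"))
    return pd.Series(lineage, index=pd.Index(nm.cell_ids, name="cell_id"),
                     name="lineage")
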