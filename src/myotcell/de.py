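"""Wilcoxon rank-sum differential expression.

Conventions follow the cluster-vs-rest marker style common in single-cell
toolkits: genes are prefiltered by expressing fraction and fold change,
tested with a two-sided Wilcoxon rank-sum (exact null for small tie-free
groups, tie- and continuity-corrected normal approximation otherwise), and
Bonferroni-adjusted over the genes in the matrix.  The fold change is the
log2 ratio of de-logged group means with a pseudocount.

The same machinery drives cluster markers, arbitrary-group comparisons,
the enzymatic-digestion blocklist, and the blocklist-filtered
tissue-vs-blood comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .config import DEConfig
from .containers import NormalizedMatrix

MARKER_COLUMNS = ["gene", "group", "p_value", "p_adjusted", "log2fc",
                  "pct_in", "pct_out"]


def wilcoxon_test(x, y, exact_mode_max_n: int = 10) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank-sum of the first sample.  The exact
    permutation null is used when both groups have at most
    ``exact_mode_max_n`` observations and the pooled values are tie-free;
    otherwise the normal approximation with tie correction and continuity
    correction.  Identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1 = x.size
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return n1 * (pooled.size + 1) / 2.0, 1.0
    no_ties = np.unique(pooled).size == pooled.size
    if max(x.size, y.size) <= exact_mode_max_n and no_ties:
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    w = float(res.statistic) + n1 * (n1 + 1) / 2.0
    return w, float(res.pvalue)


def log2_fold_change(x, y, pseudocount: float = 1.0) -> float:
    """log2 ratio of de-logged group means, with a pseudocount.

    Inputs are ln(1+x)-normalized values; means are taken on the de-logged
    scale: log2((mean(exp(x)-1)+pc) / (mean(exp(y)-1)+pc)).
    """
    mx = float(np.mean(np.expm1(np.asarray(x, dtype=float))))
    my = float(np.mean(np.expm1(np.asarray(y, dtype=float))))
    return float(np.log2((mx + pseudocount) / (my + pseudocount)))


def _group_stats(values: np.ndarray, in_mask: np.ndarray,
                 pseudocount: float) -> tuple[np.ndarray, ...]:
    """Vectorized per-gene pct and log2FC for one group-vs-rest split."""
    a = values[:, in_mask]
    b = values[:, ~in_mask]
    pct_in = (a > 0).mean(axis=1)
    pct_out = (b > 0).mean(axis=1)
    mean_a = np.expm1(a).mean(axis=1)
    mean_b = np.expm1(b).mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return pct_in, pct_out, lfc


def _test_group(nm: NormalizedMatrix, in_mask: np.ndarray, label,
                cfg: DEConfig, n_tests_total: int) -> pd.DataFrame:
    pct_in, pct_out, lfc = _group_stats(nm.values, in_mask, cfg.pseudocount)
    tested = (np.maximum(pct_in, pct_out) >= cfg.min_pct) & \
             (np.abs(lfc) >= cfg.min_abs_log2fc)
    rows = []
    for gi in np.flatnonzero(tested):
        _, p = wilcoxon_test(nm.values[gi, in_mask], nm.values[gi, ~in_mask],
                             cfg.exact_mode_max_n)
        rows.append((nm.gene_ids[gi], label, p,
                     min(1.0, p * n_tests_total), lfc[gi],
                     pct_in[gi], pct_out[gi]))
    out = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    return out.sort_values(["log2fc", "gene"], ascending=[False, True],
                           ignore_index=True)


def find_all_markers(nm: NormalizedMatrix, labels: pd.Series,
                     cfg: DEConfig | None = None) -> pd.DataFrame:
    """Cluster-vs-rest Wilcoxon markers for every cluster.

    For each cluster, genes passing the expressing-fraction and fold-change
    prefilters are tested against all remaining cells; p values are
    Bonferroni-adjusted by the number of genes in the matrix.  Records are
    sorted by log2FC within cluster.  One-cell clusters are skipped.
    """
    cfg = cfg or DEConfig()
    labels = labels.loc[list(nm.cell_ids)]
    groups = sorted(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least two clusters for marker discovery")
    tables = []
    for g in groups:
        in_mask = (labels == g).to_numpy()
        if in_mask.sum() < 2:
            warnings.warn(f"cluster {g} has fewer than 2 cells; skipped")
            continue
        tables.append(_test_group(nm, in_mask, g, cfg, nm.n_genes))
    return pd.concat(tables, ignore_index=True) if tables else \
        pd.DataFrame(columns=MARKER_COLUMNS)


def top_markers(markers: pd.DataFrame, n: int,
                alpha: float | None = None) -> pd.DataFrame:
    """Top-n up-regulated genes per group by log2FC (heatmap selection)."""
    df = markers[markers["log2fc"] > 0]
    if alpha is not None:
        df = df[df["p_adjusted"] < alpha]
    return (df.sort_values(["group", "log2fc", "gene"],
                           ascending=[True, False, True])
            .groupby("group", observed=True).head(n).reset_index(drop=True))


def de_between_groups(nm: NormalizedMatrix, grouping: pd.Series,
                      cfg: DEConfig | None = None) -> pd.DataFrame:
    """Group-vs-rest DE for an arbitrary cell grouping factor."""
    cfg = cfg or DEConfig()
    grouping = grouping.loc[list(nm.cell_ids)]
    groups = sorted(pd.unique(grouping))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = grouping.value_counts()
    if (sizes < 10).any() and (sizes > 100).any():
        warnings.warn("highly unbalanced group sizes; tests may be underpowered")
    tables = []
    for g in groups:
        in_mask = (grouping == g).to_numpy()
        if in_mask.sum() < 2:
            warnings.warn(f"group {g} has fewer than 2 cells; skipped")
            continue
        tables.append(_test_group(nm, in_mask, g, cfg, nm.n_genes))
    return pd.concat(tables, ignore_index=True)


def de_two_groups(nm: NormalizedMatrix, mask_a: np.ndarray, label_a: str,
                  cfg: DEConfig | None = None) -> pd.DataFrame:
    """One-sided table of a two-group comparison (A vs rest-of-cells)."""
    cfg = cfg or DEConfig()
    mask_a = np.asarray(mask_a, dtype=bool)
    if mask_a.sum() == 0 or (~mask_a).sum() == 0:
        raise ValueError("both arms must be nonempty")
    return _test_group(nm, mask_a, label_a, cfg, nm.n_genes)


def digestion_blocklist(nm: NormalizedMatrix, treated_mask: np.ndarray,
                        cfg: DEConfig | None = None) -> pd.DataFrame:
    """Genes perturbed by enzymatic digestion, from a treated/untreated pair.

    Cells in ``treated_mask`` were collagenase-exposed; the rest of the
    matrix is the untreated arm (both from the same compartment).  The
    blocklist holds genes with Bonferroni-adjusted p < alpha and
    |log2FC| >= min_abs_log2fc, with the direction of change recorded.
    """
    cfg = cfg or DEConfig()
    table = de_two_groups(nm, treated_mask, "collagenase", cfg)
    hits = table[(table["p_adjusted"] < cfg.alpha)
                 & (table["log2fc"].abs() >= cfg.min_abs_log2fc)].copy()
    hits["direction"] = np.where(hits["log2fc"] > 0, "up", "down")
    return hits[["gene", "log2fc", "p_value", "p_adjusted", "direction"]] \
        .reset_index(drop=True)


def tissue_vs_blood_de(nm: NormalizedMatrix, compartments: pd.Series,
                       blocklist: list[str] | pd.DataFrame | None = None,
                       cfg: DEConfig | None = None,
                       tissue: str = "muscle",
                       top_n: int = 50) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tissue-vs-blood DE with digestion-artifact genes removed first.

    Blocklist genes are dropped from the matrix BEFORE testing, so they can
    neither be reported nor absorb multiple-testing burden.  Returns the
    full marker table (tissue vs blood) and the top-``top_n`` upregulated
    genes ranked by log2FC.
    """
    cfg = cfg or DEConfig()
    if blocklist is None:
        blocked: set[str] = set()
    elif isinstance(blocklist, pd.DataFrame):
        blocked = set(blocklist["gene"])
    else:
        blocked = set(blocklist)
    keep = np.array([g not in blocked for g in nm.gene_ids])
    if not keep.any():
        raise ValueError("blocklist removes the entire gene set")
    sub = nm.subset_genes(keep)
    compartments = compartments.loc[list(sub.cell_ids)]
    present = set(compartments)
    if tissue not in present or len(present) < 2:
        raise ValueError("both compartments must be present")
    table = de_two_groups(sub, (compartments == tissue).to_numpy(), tissue, cfg)
    top = table[(table["log2fc"] > 0) & (table["p_adjusted"] < cfg.alpha)]
    top = top.sort_values(["log2fc", "gene"], ascending=[False, True]) \
        .head(top_n).reset_index(drop=True)
    return table, top
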