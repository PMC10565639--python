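"""Preranked gene-set enrichment: weighted running-sum score with a
gene-permutation null.

The enrichment score (ES) is the signed extremum of a weighted
Kolmogorov-Smirnov running sum over a ranked gene list: genes in the set
("hits") increment the sum by |score|^p normalized over hits, genes
outside it decrement by 1/(N - N_hits).  The null distribution comes from
random same-size gene sets; NES normalizes ES by the mean magnitude of
same-sign null scores.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEConfig
from .containers import NormalizedMatrix
from .de import _group_stats


@dataclass
class GseaResult:
    es: float
    nes: float
    p_value: float
    n_permutations: int
    leading_edge: list[str] = field(default_factory=list)
    running_sum: np.ndarray | None = None
    p_is_upper_bound: bool = False


def rank_genes(nm: NormalizedMatrix, labels: pd.Series, target, rest,
               cfg: DEConfig | None = None) -> pd.DataFrame:
    """Rank genes by log2FC of target clusters versus rest clusters.

    Returns a (gene, score) table in strictly descending score order with
    lexicographic tie-breaks, suitable for the preranked enrichment test.
    """
    cfg = cfg or DEConfig()
    labels = labels.loc[list(nm.cell_ids)]
    target = set(target)
    rest = set(rest)
    in_mask = labels.isin(target).to_numpy()
    out_mask = labels.isin(rest).to_numpy()
    if in_mask.sum() == 0 or out_mask.sum() == 0:
        raise ValueError("target/rest clusters select no cells")
    use = in_mask | out_mask
    sub = nm.subset_cells(use)
    _, _, lfc = _group_stats(sub.values, in_mask[use], cfg.pseudocount)
    ranked = pd.DataFrame({"gene": sub.gene_ids, "score": lfc})
    return ranked.sort_values(["score", "gene"], ascending=[False, True],
                              ignore_index=True)


def enrichment_score(ranked: pd.DataFrame, gene_set, weight: float = 1.0
                     ) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS running-sum enrichment score.

    Returns (ES, running-sum trace, leading-edge genes).  The trace has one
    entry per ranked gene; it starts from 0 and returns to 0 because both
    increment pools are normalized.  Raises if the set hits none or all of
    the ranked genes.
    """
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    hit = np.isin(genes, list(set(gene_set)))
    n = len(genes)
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must hit some but not all ranked genes")
    w = np.abs(scores) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit scores are exactly zero: fall back to equal steps
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hit) / (n - n_hit)
    trace = np.cumsum(steps)
    i_max = int(np.argmax(trace))
    i_min = int(np.argmin(trace))
    # on an exact magnitude tie take the earlier extremum, which keeps the
    # unweighted set/complement antisymmetry exact
    if trace[i_max] > -trace[i_min]:
        es = trace[i_max]
    elif trace[i_max] < -trace[i_min]:
        es = trace[i_min]
    else:
        es = trace[i_max] if i_max <= i_min else trace[i_min]
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_max + 1], hit[: i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_min:], hit[i_min:]) if h]
    return float(es), trace, leading


def _null_es(ranked: pd.DataFrame, set_size: int, n_perm, seed: int,
             weight: float) -> np.ndarray:
    genes = ranked["gene"].to_numpy()
    n = len(genes)
    if n_perm == "exhaustive":
        out = []
        for combo in itertools.combinations(range(n), set_size):
            es, _, _ = enrichment_score(ranked, genes[list(combo)], weight)
            out.append(es)
        return np.array(out)
    rng = np.random.default_rng(seed)
    out = np.empty(int(n_perm))
    for i in range(int(n_perm)):
        pick = rng.choice(n, size=set_size, replace=False)
        es, _, _ = enrichment_score(ranked, genes[pick], weight)
        out[i] = es
    return out


def gsea_permutation(ranked: pd.DataFrame, gene_set, n_perm: int | str = 1000,
                     seed: int = 0, weight: float = 1.0) -> GseaResult:
    """Permutation GSEA with a random same-size gene-set null.

    p = (1 + #{same-sign null at least as extreme}) / (1 + #{same-sign
    null}); NES = ES / mean |same-sign null ES|.  ``n_perm="exhaustive"``
    enumerates every same-size subset (feasible only for tiny lists).
    When too few null scores share the observed sign the reported p is an
    upper bound and flagged as such.
    """
    if n_perm != "exhaustive" and int(n_perm) < 100:
        raise ValueError("n_perm must be >= 100 (or 'exhaustive')")
    members = [g for g in set(gene_set) if g in set(ranked["gene"])]
    es, trace, leading = enrichment_score(ranked, members, weight)
    null = _null_es(ranked, len(members), n_perm, seed, weight)
    same_sign = null >= 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    upper_bound = False
    if n_same < 10:
        warnings.warn("too few same-sign permutations; p is an upper bound")
        upper_bound = True
    extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
    p = (1 + extreme) / (1 + n_same)
    mean_mag = float(np.abs(null[same_sign]).mean()) if n_same else np.nan
    nes = es / mean_mag if n_same and mean_mag > 0 else np.nan
    return GseaResult(es=es, nes=float(nes), p_value=float(p),
                      n_permutations=len(null), leading_edge=leading,
                      running_sum=trace, p_is_upper_bound=upper_bound)


def gsea_table(ranked: pd.DataFrame, gene_sets: dict[str, list[str]],
               n_perm: int = 1000, seed: int = 0, weight: float = 1.0
               ) -> tuple[pd.DataFrame, dict[str, GseaResult]]:
    """Run the permutation test for every gene set.

    Returns the one-row-per-set summary table and the full results
    (including running-sum traces) keyed by set name.
    """
    rows = []
    results: dict[str, GseaResult] = {}
    for name, members in gene_sets.items():
        res = gsea_permutation(ranked, members, n_perm=n_perm, seed=seed,
                               weight=weight)
        results[name] = res
        rows.append((name, res.es, res.nes, res.p_value, res.n_permutations,
                     ";".join(res.leading_edge)))
    table = pd.DataFrame(rows, columns=["gene_set", "es", "nes", "p_value",
                                        "n_permutations", "leading_edge"])
    return table, results
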