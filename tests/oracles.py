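"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (enumeration,
direct formulas) without calling the implementation under test.
"""

import itertools
from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def _combos(n: int, k: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), k)), dtype=int)


def wilcoxon_exact_p(x, y) -> float:
    """Two-sided rank-sum p by enumerating all group assignments.

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)) capped at 1, where U is the
    Mann-Whitney statistic of the first group under the permutation null.
    Assumes no ties in the pooled sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, n1 = pooled.size, x.size
    ranks = pooled.argsort().argsort() + 1  # tie-free
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    combos = _combos(n, n1)
    rank_sums = np.sort(ranks)[combos].sum(axis=1)  # ranks are 1..n
    u_all = rank_sums - n1 * (n1 + 1) / 2
    p_low = np.mean(u_all <= u_obs)
    p_high = np.mean(u_all >= u_obs)
    return float(min(1.0, 2 * min(p_low, p_high)))


def gsea_es(scores_desc, hit_mask, weight=1.0) -> float:
    """Direct evaluation of the weighted KS running-sum extremum."""
    scores = np.asarray(scores_desc, dtype=float)
    hit = np.asarray(hit_mask, dtype=bool)
    n, nh = hit.size, int(hit.sum())
    w = np.abs(scores) ** weight
    running, best = 0.0, 0.0
    for i in range(n):
        if hit[i]:
            running += w[i] / w[hit].sum()
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


def gsea_exhaustive_p(scores_desc, genes, members, weight=1.0) -> float:
    """Permutation p with every same-size gene set enumerated."""
    genes = list(genes)
    member_set = set(members)
    hit_obs = np.array([g in member_set for g in genes])
    es_obs = gsea_es(scores_desc, hit_obs, weight)
    null = []
    for combo in itertools.combinations(range(len(genes)), int(hit_obs.sum())):
        mask = np.zeros(len(genes), dtype=bool)
        mask[list(combo)] = True
        null.append(gsea_es(scores_desc, mask, weight))
    null = np.array(null)
    same = null >= 0 if es_obs >= 0 else null < 0
    extreme = int((np.abs(null[same]) >= abs(es_obs)).sum())
    return (1 + extreme) / (1 + int(same.sum()))


def modularity(edges, partition, n_nodes) -> float:
    """Newman modularity of an unweighted graph partition."""
    m = len(edges)
    deg = np.zeros(n_nodes)
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    q = 0.0
    for u, v in edges:
        if partition[u] == partition[v]:
            q += 1.0 / m
    comms = set(partition)
    for c in comms:
        d = sum(deg[i] for i in range(n_nodes) if partition[i] == c)
        q -= (d / (2 * m)) ** 2
    return q


def all_partitions(items):
    """Every set partition of a small collection (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_modularity_partition(edges, n_nodes):
    """Brute-force maximum-modularity partition of a tiny graph."""
    best_q, best_p = -np.inf, None
    for part in all_partitions(range(n_nodes)):
        labels = {}
        for ci, block in enumerate(part):
            for node in block:
                labels[node] = ci
        q = modularity(edges, labels, n_nodes)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p


def clone_partition_bruteforce(receptors) -> set[frozenset]:
    """All-pairs CDR3 comparison: cells with identical (alpha tuple, beta
    tuple) keys belong together.  Returns the set of member-sets."""
    eligible = receptors[~receptors["doublet"] & receptors["paired"]]
    cells = list(eligible.index)
    groups = []
    for c in cells:
        key = (eligible.loc[c, "alpha_cdr3s"], eligible.loc[c, "beta_cdr3s"])
        for grp in groups:
            gkey = (eligible.loc[grp[0], "alpha_cdr3s"],
                    eligible.loc[grp[0], "beta_cdr3s"])
            if key == gkey:
                grp.append(c)
                break
        else:
            groups.append([c])
    return {frozenset(g) for g in groups}
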