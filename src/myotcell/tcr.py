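"""Paired-chain TCR clonotype calling and repertoire statistics.

A clone is a set of cells sharing identical productive CDR3 amino-acid
sequences on both the alpha and beta chain; "expanded" means at least two
cells.  Cells with two productive alpha AND two productive beta chains are
sorted-well doublets and removed before clone calling; cells lacking a
productive chain on either locus cannot satisfy the paired definition and
are excluded from clone statistics (but counted in the coverage report).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .io import read_airr_rearrangements  # noqa: F401  (module surface)


def flag_tcr_doublets(chains: pd.DataFrame) -> pd.DataFrame:
    """Collapse chains per cell into receptor tuples and flag doublets.

    Returns one row per cell with sorted, deduplicated tuples of productive
    alpha and beta CDR3s, a ``doublet`` flag (>= 2 of each), and a
    ``paired`` flag (>= 1 of each).  TRG/TRD chains are ignored.
    """
    prod = chains[chains["productive"].astype(bool)
                  & chains["locus"].isin(["TRA", "TRB"])]
    rows = []
    for cell in pd.unique(chains["cell_id"]):
        sub = prod[prod["cell_id"] == cell]
        alphas = tuple(sorted(set(sub.loc[sub["locus"] == "TRA", "junction_aa"])))
        betas = tuple(sorted(set(sub.loc[sub["locus"] == "TRB", "junction_aa"])))
        rows.append((cell, alphas, betas,
                     len(alphas) >= 2 and len(betas) >= 2,
                     len(alphas) >= 1 and len(betas) >= 1))
    return pd.DataFrame(rows, columns=["cell_id", "alpha_cdr3s", "beta_cdr3s",
                                       "doublet", "paired"]).set_index("cell_id")


def call_clonotypes(receptors: pd.DataFrame, meta: pd.DataFrame,
                    clusters: pd.Series | None = None,
                    lineage: pd.Series | None = None,
                    match_mode: str = "strict") -> pd.DataFrame:
    """Group eligible cells into clonotypes by exact paired-CDR3 identity.

    Eligible cells are non-doublets with at least one productive chain on
    each locus.  In ``strict`` mode the key is the full (alpha tuple, beta
    tuple); ``relaxed`` merges clones whenever any alpha AND any beta CDR3
    match.  Returns one row per cell with clone_id (deterministic,
    first-seen order over sorted cell ids), clone_size, expanded flag and
    metadata annotations.
    """
    if match_mode not in ("strict", "relaxed"):
        raise ValueError("match_mode must be 'strict' or 'relaxed'")
    eligible = receptors[~receptors["doublet"] & receptors["paired"]]
    cells = sorted(eligible.index)
    key_of: dict[str, tuple] = {
        c: (eligible.loc[c, "alpha_cdr3s"], eligible.loc[c, "beta_cdr3s"])
        for c in cells
    }
    if match_mode == "strict":
        groups: dict[tuple, list[str]] = {}
        for c in cells:
            groups.setdefault(key_of[c], []).append(c)
        clusters_of_cells = list(groups.values())
    else:
        # union-find over cells sharing any alpha and any beta
        g = nx.Graph()
        g.add_nodes_from(cells)
        by_alpha: dict[str, list[str]] = {}
        for c in cells:
            for a in key_of[c][0]:
                by_alpha.setdefault(a, []).append(c)
        for members in by_alpha.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    if set(key_of[members[i]][1]) & set(key_of[members[j]][1]):
                        g.add_edge(members[i], members[j])
        clusters_of_cells = [sorted(cc) for cc in nx.connected_components(g)]
        clusters_of_cells.sort(key=lambda cc: cc[0])

    rows = []
    for i, members in enumerate(
        sorted(clusters_of_cells, key=lambda cc: sorted(cc)[0])
    ):
        clone_id = f"CT{i + 1:05d}"
        for c in sorted(members):
            alpha, beta = key_of[c]
            rows.append({
                "cell_id": c,
                "clone_id": clone_id,
                "alpha_cdr3s": ";".join(alpha),
                "beta_cdr3s": ";".join(beta),
                "clone_size": len(members),
                "expanded": len(members) >= 2,
            })
    table = pd.DataFrame(rows)
    if len(table) == 0:
        return pd.DataFrame(columns=["cell_id", "clone_id", "alpha_cdr3s",
                                     "beta_cdr3s", "clone_size", "expanded",
                                     "patient", "compartment", "timepoint"])
    table = table.set_index("cell_id")
    for col in ("patient", "compartment", "timepoint", "treatment"):
        if col in meta.columns:
            table[col] = meta.loc[table.index, col]
    if clusters is not None:
        table["cluster"] = clusters.reindex(table.index)
    if lineage is not None:
        table["lineage"] = lineage.reindex(table.index)
    return table


def coverage_report(receptors: pd.DataFrame) -> dict:
    """How many cells had usable receptors at each step."""
    return {
        "cells_with_chains": int(len(receptors)),
        "doublets_removed": int(receptors["doublet"].sum()),
        "unpaired_excluded": int((~receptors["doublet"]
                                  & ~receptors["paired"]).sum()),
        "eligible": int((~receptors["doublet"] & receptors["paired"]).sum()),
    }


def expansion_summary(clones: pd.DataFrame) -> pd.DataFrame:
    """Per-sample clonal expansion: fraction of cells in expanded clones.

    One row per (patient, compartment, timepoint): number of cells with a
    valid paired key, cell-level expanded fraction, clone-level expanded
    fraction (expanded clones / distinct clones), and a clone-size
    histogram for stacked-bar rendering.
    """
    rows = []
    keys = ["patient", "compartment", "timepoint"]
    for sample, sub in clones.groupby(keys, observed=True):
        # clone size within this sample (a shared clone may be larger overall)
        local = sub.groupby("clone_id").size()
        n_cells = len(sub)
        expanded_cells = int(sub["expanded"].sum())
        n_clones = local.size
        expanded_clones = int((sub.groupby("clone_id")["expanded"].first()).sum())
        hist = local.value_counts().sort_index()
        rows.append((*sample, n_cells, expanded_cells,
                     expanded_cells / n_cells if n_cells else 0.0,
                     n_clones, expanded_clones,
                     expanded_clones / n_clones if n_clones else 0.0,
                     ";".join(f"{s}:{c}" for s, c in hist.items())))
    return pd.DataFrame(rows, columns=[*keys, "n_cells", "n_expanded_cells",
                                       "expanded_cell_fraction", "n_clones",
                                       "n_expanded_clones",
                                       "expanded_clone_fraction",
                                       "clone_size_histogram"])


def clone_sharing(clones: pd.DataFrame, axis: str = "compartment"
                  ) -> pd.DataFrame:
    """Which axis values (compartments or patients) each clone spans.

    ``compartment`` mode lists muscle/PB-shared clones; ``patient`` mode
    flags any clone present in >= 2 patients as public (a finding worth a
    prominent report line, since shared specificities across patients are
    unexpected for private repertoires).
    """
    if axis not in ("compartment", "patient"):
        raise ValueError("axis must be 'compartment' or 'patient'")
    rows = []
    for clone_id, sub in clones.groupby("clone_id"):
        values = sorted(set(sub[axis]))
        rows.append((clone_id, len(sub), ";".join(values), len(values) >= 2))
    shared_col = "shared" if axis == "compartment" else "public"
    return pd.DataFrame(rows, columns=["clone_id", "clone_size", axis + "s",
                                       shared_col])


def clone_persistence(clones: pd.DataFrame) -> pd.DataFrame:
    """Clones observed at both timepoints of longitudinal patients.

    One row per (patient, compartment, clone) for patients with >= 2
    timepoints, with member counts at each timepoint, a ``persistent`` flag
    and the baseline expansion status.  Single-timepoint patients simply
    contribute no rows.
    """
    rows = []
    for patient, psub in clones.groupby("patient"):
        tps = sorted(set(psub["timepoint"]))
        if len(tps) < 2:
            continue
        t1, t2 = tps[0], tps[1]
        for comp, csub in psub.groupby("compartment"):
            for clone_id, sub in csub.groupby("clone_id"):
                n1 = int((sub["timepoint"] == t1).sum())
                n2 = int((sub["timepoint"] == t2).sum())
                rows.append((patient, comp, clone_id, t1, n1, t2, n2,
                             n1 > 0 and n2 > 0, n1 >= 2))
    return pd.DataFrame(rows, columns=["patient", "compartment", "clone_id",
                                       "timepoint_1", "n_cells_t1",
                                       "timepoint_2", "n_cells_t2",
                                       "persistent", "expanded_at_baseline"])


def build_clone_network(clones: pd.DataFrame,
                        include_singletons: bool = False) -> nx.Graph:
    """Cell-level clone network: a clique per clone.

    Nodes are member cells of expanded clones (singletons optional),
    annotated with patient/compartment/timepoint and, when available,
    cluster and lineage; every pair of cells in a clone is connected, so a
    clone of size s contributes s(s-1)/2 edges carrying its clone id.
    """
    g = nx.Graph()
    use = clones if include_singletons else clones[clones["expanded"]]
    attr_cols = [c for c in ("patient", "compartment", "timepoint", "cluster",
                             "lineage") if c in use.columns]
    for cell, row in use.iterrows():
        g.add_node(cell, clone_id=row["clone_id"],
                   **{c: ("" if pd.isna(row[c]) else str(row[c]))
                      for c in attr_cols})
    for clone_id, sub in use.groupby("clone_id"):
        members = sorted(sub.index)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                g.add_edge(members[i], members[j], clone_id=clone_id)
    return g


def network_edge_list(g: nx.Graph) -> pd.DataFrame:
    rows = [(u, v, d.get("clone_id", "")) for u, v, d in
            sorted(g.edges(data=True))]
    return pd.DataFrame(rows, columns=["cell_a", "cell_b", "clone_id"])
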