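"""Paired-chain clonotype calling, repertoire statistics and the network."""

import numpy as np
import pandas as pd
import pytest

from myotcell import tcr
import oracles


def chains_frame(rows):
    return pd.DataFrame(rows, columns=["cell_id", "locus", "productive",
                                       "junction_aa", "v_call", "j_call"])


def meta_frame(cells, **cols):
    base = {"patient": "P1", "compartment": "muscle", "timepoint": "T1",
            "treatment": "early"}
    base.update(cols)
    return pd.DataFrame({k: (v if isinstance(v, list) else [v] * len(cells))
                         for k, v in base.items()},
                        index=pd.Index(cells, name="cell_id"))


class TestDoublets:
    def test_two_alpha_two_beta_is_doublet(self):
        rows = [("c1", "TRA", True, "CA1F", "TRAV1", "TRAJ1"),
                ("c1", "TRA", True, "CA2F", "TRAV2", "TRAJ1"),
                ("c1", "TRB", True, "CB1F", "TRBV1", "TRBJ1"),
                ("c1", "TRB", True, "CB2F", "TRBV1", "TRBJ2")]
        rec = tcr.flag_tcr_doublets(chains_frame(rows))
        assert bool(rec.loc["c1", "doublet"])

    def test_two_alpha_one_beta_is_kept(self):
        rows = [("c1", "TRA", True, "CA1F", "TRAV1", "TRAJ1"),
                ("c1", "TRA", True, "CA2F", "TRAV2", "TRAJ1"),
                ("c1", "TRB", True, "CB1F", "TRBV1", "TRBJ1")]
        rec = tcr.flag_tcr_doublets(chains_frame(rows))
        assert not bool(rec.loc["c1", "doublet"])
        assert bool(rec.loc["c1", "paired"])

    def test_nonproductive_chains_ignored(self):
        rows = [("c1", "TRA", True, "CA1F", "TRAV1", "TRAJ1"),
                ("c1", "TRA", False, "CA2F", "TRAV2", "TRAJ1"),
                ("c1", "TRB", True, "CB1F", "TRBV1", "TRBJ1"),
                ("c1", "TRB", False, "CB2F", "TRBV1", "TRBJ2")]
        rec = tcr.flag_tcr_doublets(chains_frame(rows))
        assert not bool(rec.loc["c1", "doublet"])
        assert rec.loc["c1", "alpha_cdr3s"] == ("CA1F",)

    def test_unpaired_cell_excluded_from_clones(self):
        rows = [("c1", "TRA", True, "CA1F", "TRAV1", "TRAJ1")]
        rec = tcr.flag_tcr_doublets(chains_frame(rows))
        assert not bool(rec.loc["c1", "paired"])
        clones = tcr.call_clonotypes(rec, meta_frame(["c1"]))
        assert len(clones) == 0


class TestCloneCalling:
    def _toy(self):
        rows = [("c1", "TRA", True, "CAVRF", "TRAV1", "TRAJ1"),
                ("c1", "TRB", True, "CASSF", "TRBV1", "TRBJ1"),
                ("c2", "TRA", True, "CAVRF", "TRAV1", "TRAJ1"),
                ("c2", "TRB", True, "CASSF", "TRBV1", "TRBJ1"),
                ("c3", "TRA", True, "CAVXF", "TRAV2", "TRAJ1"),
                ("c3", "TRB", True, "CASSF", "TRBV1", "TRBJ1")]
        return tcr.flag_tcr_doublets(chains_frame(rows))

    def test_shared_pair_forms_expanded_clone(self):
        rec = self._toy()
        clones = tcr.call_clonotypes(rec, meta_frame(["c1", "c2", "c3"]))
        assert clones.loc["c1", "clone_id"] == clones.loc["c2", "clone_id"]
        assert clones.loc["c3", "clone_id"] != clones.loc["c1", "clone_id"]
        assert bool(clones.loc["c1", "expanded"])
        assert not bool(clones.loc["c3", "expanded"])

    def test_input_order_invariance(self):
        rec = self._toy()
        clones_a = tcr.call_clonotypes(rec, meta_frame(["c1", "c2", "c3"]))
        rec_shuffled = rec.iloc[[2, 0, 1]]
        clones_b = tcr.call_clonotypes(rec_shuffled,
                                       meta_frame(["c1", "c2", "c3"]))
        for cell in ("c1", "c2", "c3"):
            assert (clones_a.loc[cell, "clone_id"]
                    == clones_b.loc[cell, "clone_id"])

    def test_relaxed_mode_merges_on_any_chain_match(self):
        rows = [("c1", "TRA", True, "CA1F", "TRAV1", "TRAJ1"),
                ("c1", "TRA", True, "CA2F", "TRAV2", "TRAJ1"),
                ("c1", "TRB", True, "CB1F", "TRBV1", "TRBJ1"),
                ("c2", "TRA", True, "CA1F", "TRAV1", "TRAJ1"),
                ("c2", "TRB", True, "CB1F", "TRBV1", "TRBJ1")]
        rec = tcr.flag_tcr_doublets(chains_frame(rows))
        strict = tcr.call_clonotypes(rec, meta_frame(["c1", "c2"]))
        assert strict.loc["c1", "clone_id"] != strict.loc["c2", "clone_id"]
        relaxed = tcr.call_clonotypes(rec, meta_frame(["c1", "c2"]),
                                      match_mode="relaxed")
        assert relaxed.loc["c1", "clone_id"] == relaxed.loc["c2", "clone_id"]

    def test_matches_bruteforce_oracle_on_cohort(self, cohort_tcr, cohort):
        chains, truth = cohort_tcr
        matrix, _ = cohort
        sub_cells = set(pd.unique(chains["cell_id"])[:200])
        sub = chains[chains["cell_id"].isin(sub_cells)]
        rec = tcr.flag_tcr_doublets(sub)
        clones = tcr.call_clonotypes(rec, matrix.cell_meta)
        called = {frozenset(grp.index)
                  for _, grp in clones.groupby("clone_id")}
        assert called == oracles.clone_partition_bruteforce(rec)

    def test_partition_and_truth_round_trip(self, cohort_tcr, cohort):
        chains, truth = cohort_tcr
        matrix, _ = cohort
        rec = tcr.flag_tcr_doublets(chains)
        clones = tcr.call_clonotypes(rec, matrix.cell_meta)
        # partition property: every eligible cell in exactly one clone
        eligible = rec[~rec["doublet"] & rec["paired"]]
        assert set(clones.index) == set(eligible.index)
        assert clones.groupby("clone_id")["clone_size"].first().sum() \
            == len(eligible)
        # planted partition recovered exactly
        planted = {}
        for cell, cid in truth.clone_membership.items():
            if cid is not None:
                planted.setdefault(cid, set()).add(cell)
        assert {frozenset(v) for v in planted.values()} == \
            {frozenset(grp.index) for _, grp in clones.groupby("clone_id")}
        assert truth.doublet_cells.isdisjoint(set(clones.index))


class TestRepertoireStats:
    def _clones(self, sizes, meta_cols=None):
        rows = []
        cells = []
        i = 0
        for k, size in enumerate(sizes):
            for _ in range(size):
                i += 1
                cells.append(f"c{i}")
                rows.append({"cell_id": f"c{i}", "clone_id": f"CT{k}",
                             "alpha_cdr3s": f"A{k}", "beta_cdr3s": f"B{k}",
                             "clone_size": size, "expanded": size >= 2})
        df = pd.DataFrame(rows).set_index("cell_id")
        meta = meta_frame(cells, **(meta_cols or {}))
        for col in ("patient", "compartment", "timepoint"):
            df[col] = meta[col]
        return df

    def test_expansion_fraction_arithmetic(self):
        clones = self._clones([4, 2, 1, 1, 1, 1])
        table = tcr.expansion_summary(clones)
        assert len(table) == 1
        assert table.loc[0, "expanded_cell_fraction"] == pytest.approx(0.6)
        assert table.loc[0, "n_cells"] == 10

    def test_all_singletons_zero(self):
        table = tcr.expansion_summary(self._clones([1, 1, 1]))
        assert table.loc[0, "expanded_cell_fraction"] == 0.0

    def test_compartment_sharing_and_publicity(self):
        clones = self._clones([2], meta_cols={"compartment": ["muscle", "PB"]})
        shared = tcr.clone_sharing(clones, axis="compartment")
        assert bool(shared.loc[0, "shared"])
        public = tcr.clone_sharing(clones, axis="patient")
        assert not bool(public.loc[0, "public"])
        two_pat = self._clones([2], meta_cols={"patient": ["P1", "P2"]})
        assert bool(tcr.clone_sharing(two_pat, axis="patient")
                    .loc[0, "public"])

    def test_persistence_counts(self):
        clones = self._clones([5], meta_cols={
            "timepoint": ["T1", "T1", "T1", "T2", "T2"]})
        table = tcr.clone_persistence(clones)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["n_cells_t1"], row["n_cells_t2"]) == (3, 2)
        assert bool(row["persistent"]) and bool(row["expanded_at_baseline"])

    def test_single_timepoint_patient_empty(self):
        table = tcr.clone_persistence(self._clones([3]))
        assert table.empty

    def test_cohort_sharing_matches_truth(self, cohort_tcr, cohort):
        chains, truth = cohort_tcr
        matrix, _ = cohort
        rec = tcr.flag_tcr_doublets(chains)
        clones = tcr.call_clonotypes(rec, matrix.cell_meta)
        shared = tcr.clone_sharing(clones, axis="compartment")
        called_shared = set(shared.loc[shared["shared"], "clone_id"])
        # map called clone ids to planted ids via any member cell
        members_of = clones.groupby("clone_id").groups
        truth_shared = 0
        for cid in called_shared:
            cell = list(members_of[cid])[0]
            planted = truth.clone_attributes[truth.clone_membership[cell]]
            assert len(planted["compartments"]) == 2
            truth_shared += 1
        planted_shared = sum(1 for a in truth.clone_attributes.values()
                             if len(a["compartments"]) == 2)
        assert truth_shared == planted_shared
        publicity = tcr.clone_sharing(clones, axis="patient")
        assert not publicity["public"].any()


class TestNetwork:
    def test_clique_edge_counts(self):
        clones = TestRepertoireStats()._clones([3])
        net = tcr.build_clone_network(clones)
        assert net.number_of_nodes() == 3
        assert net.number_of_edges() == 3

    def test_disjoint_clones_components(self):
        clones = TestRepertoireStats()._clones([2, 2])
        net = tcr.build_clone_network(clones)
        import networkx as nx
        assert net.number_of_nodes() == 4
        assert net.number_of_edges() == 2
        assert nx.number_connected_components(net) == 2

    def test_no_expanded_clones_empty_network(self):
        clones = TestRepertoireStats()._clones([1, 1])
        net = tcr.build_clone_network(clones)
        assert net.number_of_nodes() == 0
        with_singletons = tcr.build_clone_network(clones,
                                                  include_singletons=True)
        assert with_singletons.number_of_nodes() == 2

    def test_edge_identity_on_cohort(self, cohort_tcr, cohort):
        chains, _ = cohort_tcr
        matrix, _ = cohort
        rec = tcr.flag_tcr_doublets(chains)
        clones = tcr.call_clonotypes(rec, matrix.cell_meta)
        net = tcr.build_clone_network(clones)
        sizes = clones.loc[clones["expanded"]].groupby("clone_id").size()
        assert net.number_of_edges() == int((sizes * (sizes - 1) // 2).sum())
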