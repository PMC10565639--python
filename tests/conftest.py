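"""Shared fixtures: a small synthetic cohort and derived stage outputs."""

import numpy as np
import pandas as pd
import pytest

from myotcell import cluster as cl
from myotcell import qc
from myotcell import simulate as sim
from myotcell.config import SimConfig
from myotcell.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def cohort_config() -> SimConfig:
    return SimConfig(seed=11, n_cells_per_sample=60,
                     n_digestion_cells_per_arm=50)


@pytest.fixture(scope="session")
def cohort(cohort_config):
    """(ExpressionMatrix, GroundTruth) for a small default cohort."""
    return sim.simulate_expression(cohort_config)


@pytest.fixture(scope="session")
def cohort_tcr(cohort_config, cohort):
    """(chains table, updated GroundTruth) for the cohort repertoire."""
    matrix, truth = cohort
    import copy

    truth = copy.deepcopy(truth)
    chains, truth = sim.simulate_tcr(cohort_config, truth, matrix.cell_meta)
    return chains, truth


@pytest.fixture(scope="session")
def clean_cohort(cohort):
    """QC-passed, family-filtered matrix plus the QC report."""
    matrix, truth = cohort
    filtered, report = qc.apply_cell_filters(matrix)
    clean = qc.drop_gene_families(filtered)
    return clean, report


@pytest.fixture(scope="session")
def muscle_nm(cohort, clean_cohort):
    """Normalized muscle-compartment patient cells with planted labels."""
    _, truth = cohort
    clean, _ = clean_cohort
    nm = cl.normalize_cp10k_log(clean)
    mask = ((nm.cell_meta["compartment"] == "muscle")
            & (~nm.cell_meta["treatment"].isin(["collagenase", "untreated"]))
            ).to_numpy()
    sub = nm.subset_cells(mask)
    labels = pd.Series([truth.cell_cluster[c] for c in sub.cell_ids],
                       index=pd.Index(sub.cell_ids, name="cell_id"))
    return sub, labels


def toy_matrix(values, genes, cells=None, meta=None, counts=None):
    """Build a small ExpressionMatrix with default metadata."""
    values = np.asarray(values, dtype=float)
    if cells is None:
        cells = [f"c{i + 1}" for i in range(values.shape[1])]
    if meta is None:
        meta = pd.DataFrame(
            {
                "patient": "P1",
                "compartment": "muscle",
                "timepoint": "T1",
                "batch": "B1",
                "treatment": "early",
            },
            index=pd.Index(cells, name="cell_id"),
        )
    return ExpressionMatrix(values=values, counts=counts,
                            gene_ids=np.array(genes, dtype=object),
                            cell_ids=np.array(cells, dtype=object),
                            cell_meta=meta)
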