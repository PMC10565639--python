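"""Typed configuration objects with validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


def _from_dict(cls, data: dict[str, Any]):
    """Build a dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown keys for {cls.__name__}: {', '.join(sorted(unknown))}"
        )
    return cls(**data)


@dataclass
class QCThresholds:
    """Numeric gates of the cell-filter cascade.

    Defaults follow the full-length scRNA-seq convention for plate-sorted
    T cells: gene-count window 1,000-12,000; molecule window 600,000-
    8,000,000; at most 35% mitochondrial content; a T-cell identity gate
    (some CD3 subunit >= 5 in the matrix's expression units); exclusion of
    cells expressing myeloid/B-cell markers (CD14/CD19/CD22/CD300E > 5) or
    hemoglobin (HBA1+HBA2 > 2,500, erythrocyte contamination).
    """

    min_genes: int = 1000
    max_genes: int = 12000
    min_molecules: int = 600_000
    max_molecules: int = 8_000_000
    max_mito_pct: float = 35.0
    cd3_min_rpkm: float = 5.0
    contaminant_max_rpkm: float = 5.0
    hba_max: float = 2500.0
    # "max": keep a cell if any CD3 subunit clears cd3_min_rpkm;
    # "all": keep only if all three do.
    cd3_mode: str = "max"
    # "sum": HBA1+HBA2 > hba_max fails; "both": both genes must exceed it.
    hba_mode: str = "sum"

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ConfigError("min_genes must be < max_genes")
        if not self.min_molecules < self.max_molecules:
            raise ConfigError("min_molecules must be < max_molecules")
        if not 0 < self.max_mito_pct < 100:
            raise ConfigError("max_mito_pct must be in (0, 100)")
        if self.cd3_mode not in ("max", "all"):
            raise ConfigError("cd3_mode must be 'max' or 'all'")
        if self.hba_mode not in ("sum", "both"):
            raise ConfigError("hba_mode must be 'sum' or 'both'")

    @classmethod
    def from_dict(cls, data: dict) -> "QCThresholds":
        return _from_dict(cls, data)


@dataclass
class DEConfig:
    """Conventions for Wilcoxon differential expression.

    min_pct and min_abs_log2fc prefilter genes before testing; pseudocount
    enters the fold-change ratio of de-logged means; Bonferroni adjustment
    uses the number of genes in the matrix.  exact_mode_max_n is the largest
    per-group size at which the exact rank-sum null is used (ties force the
    normal approximation).
    """

    min_pct: float = 0.1
    min_abs_log2fc: float = 0.25
    pseudocount: float = 1.0
    p_adjust: str = "bonferroni"
    exact_mode_max_n: int = 10
    alpha: float = 0.05
    top_n_report: int = 7

    def __post_init__(self) -> None:
        if not 0 <= self.min_pct <= 1:
            raise ConfigError("min_pct must be in [0, 1]")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be > 0")
        if self.p_adjust not in ("bonferroni",):
            raise ConfigError(f"unsupported p_adjust method: {self.p_adjust}")
        if not 0 <= self.alpha <= 1:
            raise ConfigError("alpha must be in [0, 1]")

    @classmethod
    def from_dict(cls, data: dict) -> "DEConfig":
        return _from_dict(cls, data)


def _default_timepoints() -> dict[str, list[str]]:
    # two of seven patients were re-sampled after treatment
    return {
        "P1": ["T1", "T2"],
        "P2": ["T1", "T2"],
        "P3": ["T1"],
        "P4": ["T1"],
        "P5": ["T1"],
        "P6": ["T1"],
        "P7": ["T1"],
    }


def _default_offender_rates() -> dict[str, float]:
    return {
        "low_genes": 0.03,
        "high_mito": 0.04,
        "non_t_contaminant": 0.03,
        "rbc": 0.02,
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic patient cohort.

    The generator plants cluster-structured negative-binomial expression
    with marker programs, per-batch shifts, digestion-responsive genes,
    low-quality offender cells, and a clonal paired-chain TCR repertoire
    with cross-compartment sharing, timepoint persistence and 2a2b doublet
    wells.  Every planted feature is recorded in a ground-truth object.
    """

    n_patients: int = 7
    compartments: list[str] = field(default_factory=lambda: ["muscle", "PB"])
    timepoints_per_patient: dict[str, list[str]] = field(
        default_factory=_default_timepoints
    )
    n_cells_per_sample: int = 120
    n_genes: int = 1500
    n_clusters: int = 5
    markers_per_cluster: int = 20
    marker_log2_effect: float = 3.0
    nb_dispersion: float = 0.5
    library_size_lognormal: tuple[float, float] = (14.3, 0.2)
    mito_fraction_beta: tuple[float, float] = (2.0, 40.0)
    mito_fraction_beta_offender: tuple[float, float] = (30.0, 15.0)
    offender_rates: dict[str, float] = field(default_factory=_default_offender_rates)
    batch_shift_sd: float = 0.3
    n_collagenase_genes: int = 30
    collagenase_log2_effect: float = 2.0
    n_digestion_cells_per_arm: int = 60
    clone_size_geometric_p: float = 0.45
    clone_size_max: int = 8
    expanded_cell_fraction: float = 0.35
    expanded_clone_cluster_bias: dict[int, float] = field(
        default_factory=lambda: {1: 3.0, 2: 3.0}
    )
    share_across_compartment_prob: float = 0.6
    persist_prob: float = 0.5
    tcr_doublet_rate: float = 0.03
    nonproductive_chain_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "share_across_compartment_prob": self.share_across_compartment_prob,
            "persist_prob": self.persist_prob,
            "tcr_doublet_rate": self.tcr_doublet_rate,
            "nonproductive_chain_rate": self.nonproductive_chain_rate,
            "clone_size_geometric_p": self.clone_size_geometric_p,
            **{f"offender_rates.{k}": v for k, v in self.offender_rates.items()},
        }
        for name, v in probs.items():
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if sum(self.offender_rates.values()) >= 1:
            raise ConfigError("offender rates must sum to < 1")
        if self.n_clusters < 2:
            raise ConfigError("n_clusters must be >= 2")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if not 0 <= self.expanded_cell_fraction <= 0.9:
            raise ConfigError("expanded_cell_fraction must be in [0, 0.9]")
        if self.clone_size_max < 2:
            raise ConfigError("clone_size_max must be >= 2")
        known = {f"P{i + 1}" for i in range(self.n_patients)}
        extra = set(self.timepoints_per_patient) - known
        if extra:
            raise ConfigError(f"timepoints given for unknown patients: {sorted(extra)}")

    @property
    def patients(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_patients)]

    def timepoints(self, patient: str) -> list[str]:
        return self.timepoints_per_patient.get(patient, ["T1"])

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        for key in ("library_size_lognormal", "mito_fraction_beta",
                    "mito_fraction_beta_offender"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "expanded_clone_cluster_bias" in data:
            data["expanded_clone_cluster_bias"] = {
                int(k): float(v)
                for k, v in data["expanded_clone_cluster_bias"].items()
            }
        return _from_dict(cls, data)
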