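# myotcell

Single-cell analysis of T cells infiltrating inflamed skeletal muscle and
circulating in paired peripheral blood (PB), as encountered in idiopathic
inflammatory myopathies (IIM): sorted-well quality control, normalization
and graph clustering, Wilcoxon marker discovery, tissue-resident-memory
(T_RM) signature enrichment, digestion-artifact filtering before
tissue-vs-blood differential expression, and paired-chain TCR clonotype
analysis (expansion, cross-compartment sharing, longitudinal persistence,
clone networks).

The package is aimed at analysts working with plate-sorted full-length
scRNA-seq of T cells (RPKM-like units plus raw counts) together with
per-cell TCR assemblies in AIRR Rearrangement format. Because patient data
of this kind is access-restricted, the package ships a first-class
synthetic-cohort generator that plants every feature the pipeline is
supposed to recover — offender cells for each QC gate, marker programs,
batch shifts, collagenase-responsive genes, and a clonal repertoire — and
records the ground truth, so the whole pipeline is testable end to end
with no download.

## Methods at a glance

- **QC gates** (per cell): 1,000 ≤ detected genes ≤ 12,000; 600,000 ≤
  molecules ≤ 8,000,000; mitochondrial content ≤ 35%;
  max(CD3E, CD3D, CD3G) ≥ 5 (T-cell identity); CD14/CD19/CD22/CD300E ≤ 5
  (myeloid/B contamination); HBA1+HBA2 ≤ 2,500 (erythrocytes). TCR-segment
  and ribosomal gene families are then removed so receptor usage and
  technical covariation cannot drive clustering.
- **Normalization**: counts per 10,000 with natural log,
  `v = ln(1 + 10^4 x / Σx)`.
- **Clustering**: per-compartment PCA (8 PCs muscle, 7 PCs blood), optional
  per-batch PC-mean centering, shared-nearest-neighbor graph (Jaccard
  weights, prune 1/15) and seeded Louvain modularity optimization.
- **Markers**: two-sided Wilcoxon rank-sum per gene, cluster vs rest, with
  `log2FC = log2((mean(e^x−1)+1)/(mean(e^y−1)+1))`, expressing-fraction
  and fold-change prefilters, and Bonferroni adjustment.
- **Enrichment**: preranked GSEA — weighted Kolmogorov–Smirnov running sum
  (ES), gene-permutation null, NES and permutation p.
- **Clonotypes**: a clone is ≥1 cell sharing identical productive CDR3
  amino-acid sequences on both TCRα and TCRβ; 2α2β cells are sorted-well
  doublets and removed; "expanded" means ≥2 cells.

## Worked example

```bash
cat > cfg.yaml <<EOF
outdir: demo
simulate:
  seed: 5
EOF
myotcell run-all --config cfg.yaml
```

This simulates the default cohort (7 patients × muscle/PB, two patients
re-sampled after treatment, 120 cells per sample plus two
collagenase-digestion arms), then runs every stage. Typical output:

```
[qc] {'cells_in': 2280, 'cells_pass': 2002, 'genes_in': 1500,
      'genes_after_family_removal': 1454, ...}
[cluster] {'muscle': {'n_cells': 935, 'n_clusters': 5, 'modularity': 0.797, ...},
           'PB': {'n_cells': 947, 'n_clusters': 7, 'modularity': 0.749, ...}}
[de] {'markers_muscle': 534, 'markers_PB': 996, 'blocklist_genes': 30,
      'tissue_de_genes': 100, 'top50': 27, ...}
[gsea] {'target_clusters': [2, 4], 'gene_sets': ['synthetic_trm_up', ...]}
[tcr] {'cells_with_chains': 1882, 'doublets_removed': 44, 'eligible': 1838,
       'clonotypes': 1384, 'expanded_clonotypes': 196, 'public_clones': 0}
```

Reading these numbers: 278 of 2,280 simulated cells fail a QC gate (the
planted offenders); the 30 collagenase-responsive genes are identified
from the digestion arms and excluded before the muscle-vs-blood
comparison, whose top-50 upregulated list (27 genes reach Bonferroni
significance here) is then dominated by the planted tissue-residency
program; `gsea_results.tsv` shows the T_RM demo set with ES = 1.0,
NES ≈ 1.95 and permutation p ≈ 0.002 on the T_RM-clusters-vs-rest
ranking; and 196 expanded clones cover 39% of muscle cells with paired
chains (32% in blood), with no clone shared between patients. Stage outputs land in `demo/` as
TSV/GraphML/JSON files (`qc_report.tsv`, `clusters.tsv`, `markers.tsv`,
`blocklist.tsv`, `top50_up.tsv`, `gsea_results.tsv`, `clonotypes.tsv`,
`expansion.tsv`, `sharing.tsv`, `persistence.tsv`,
`clone_network.graphml`, `report.json`).

To analyze real data instead, replace the `simulate:` block with an
`inputs:` block pointing at `matrix.mtx` + `genes.tsv` + `barcodes.tsv` +
`cell_meta.tsv` (and optionally `counts.mtx`, an AIRR TSV and a GMT file);
see `docs/methods.md` for the format contracts.

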