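# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic cohort does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model

The pipeline operates on a genes × cells matrix in RPKM-like units
(length-normalized full-length scRNA-seq) with an optional parallel
raw-count view, plus per-cell metadata (patient, compartment muscle/PB,
timepoint, sequencing batch, treatment status). Expression thresholds
(the CD3 / contaminant / hemoglobin gates) are evaluated on the RPKM-like
view; molecule totals and mitochondrial fractions use the raw-count view
when present, falling back to the expression view with a logged unit
warning. Matrices travel as MatrixMarket coordinate files with gene /
barcode label files; TCR chains as AIRR Rearrangement TSV; gene sets as
GMT.

## Quality control

A cell fails if ANY gate trips, and every tripped gate is recorded:

| gate | default | rationale |
|---|---|---|
| min/max detected genes | 1,000 / 12,000 | degraded wells / multiplets |
| min/max molecules | 6×10⁵ / 8×10⁶ | library-size window for full-length plates |
| mitochondrial % | ≤ 35 | stressed or dying cells |
| CD3 identity | max(CD3E,CD3D,CD3G) ≥ 5 | sorted T cells only |
| contaminants | CD14/CD19/CD22/CD300E ≤ 5 | myeloid / B-cell wells |
| hemoglobin | HBA1+HBA2 ≤ 2,500 | erythrocyte contamination |

Two deliberately resolved ambiguities: the CD3 gate keeps a cell when the
*maximum* of the three subunits clears the threshold (a cell expressing
any CD3 chain is a T cell; an all-three mode is configurable), and the
hemoglobin rule applies to the *sum* of HBA1 and HBA2 in the matrix's
native units (a both-exceed mode is configurable). All-zero cells have
mito % defined as 0 (they already fail the gene floor). Gene-family
removal (TCR segment genes `TR[ABGD][VDJC]*`, cytosolic ribosomal
`RPL*/RPS*`; mitochondrial `MT-*` optional) happens after cell filtering,
so detected-gene counts refer to the full gene universe. Only cytosolic
ribosomal genes are dropped by default; mito-ribosomal `MRPL/MRPS` remain
(configurable via regex rules). Deconvolution-based size-factor exclusion
is not reproduced; its practical effect (dropping near-empty wells) is
covered by the gene/molecule floors.

## Normalization, embedding, clustering

Normalization is counts-per-10,000 with a natural log; the invariant
`Σ_g (e^v − 1) = 10⁴` holds per cell to 1e-6 relative and is tested. PCA
centers and (by default) unit-variance scales genes; zero-variance genes
are left at zero rather than divided out; the sign of each axis is fixed
by making its largest-magnitude loading positive, so embeddings are
solver-independent. Components beyond the numerical rank are returned as
exact zeros; asking for more components than `min(genes, cells)` is an
error. Defaults use 8 PCs for muscle and 7 for blood, reflecting the
different elbow depths of the two compartments; no automatic elbow
detection is attempted. Highly-variable-gene selection is off by default —
all retained genes feed PCA.

Batch adjustment is a deliberately simple, testable contract: each
sequencing batch's centroid in PC space is translated onto the global
centroid, per component. This removes additive batch offsets exactly,
never changes within-batch geometry, and is the identity for a single
batch; one-cell batches are left unshifted with a warning. It is *not* a
reimplementation of mixture-model integration methods and is named
`center` in configs to make that clear.

Cells are clustered on a shared-nearest-neighbor graph (k = 20 Euclidean
neighbors including self, Jaccard edge weights, pruned below 1/15) with
Louvain modularity optimization at resolution 1.0, via python-igraph with
a seeded RNG; labels are relabelled 1..C by decreasing cluster size.
Because neither k, resolution, nor gene scaling is canonical, recovering a
specific number of clusters on real data is not a contract; recovery of
*planted* partitions (ARI) is.

CD4/CD8 lineage is a per-cell rule on normalized expression: CD8 if
max(CD8A, CD8B) exceeds CD4 and is positive, CD4 symmetrically, otherwise
double-negative (ties at positive values are DN).

## Differential expression

Per gene, a two-sided Wilcoxon rank-sum compares the group against the
rest. The exact permutation null is used when both groups have ≤ 10
observations and the pooled values are tie-free; otherwise the normal
approximation with midranks, tie correction and continuity correction
(identical constant samples give p = 1). Fold change de-logs the
normalized values: `log2((mean(e^x−1)+1)/(mean(e^y−1)+1))` — the
pseudocount of 1 bounds the ratio for silent genes. Genes are prefiltered
(expressing fraction ≥ 0.1 on either side, |log2FC| ≥ 0.25) before
testing; Bonferroni adjustment uses the number of genes in the matrix, so
the adjusted p is conservative with respect to the prefilter. Reported
p-value display cut-offs in figures are post-hoc filters, never the
selection rule.

The digestion blocklist is computed from a collagenase-treated vs
untreated pair of PB arms: genes with adjusted p < 0.05 and |log2FC| ≥
0.25, direction recorded. Tissue-vs-blood DE removes blocklist genes
*before* testing — they can neither appear in results nor absorb
multiple-testing burden — then reports the full table and the top-50
upregulated genes by log2FC among adjusted-significant genes.

## Signature enrichment

The preranked statistic is per-gene log2FC of target clusters vs rest
(signed −log10 p is deliberately not the default: fold change matches the
ranking used for marker display). The enrichment score is the signed
extremum of the weighted Kolmogorov–Smirnov running sum (hit increments
`|s|^p / Σ_hits |s|^p` with p = 1, miss decrements `1/(N − N_hits)`); on
an exact magnitude tie between the positive and negative extremum the
earlier one is taken, which keeps the unweighted set/complement
antisymmetry exact. The null is gene-set permutation (random same-size
sets); `n_perm="exhaustive"` enumerates all subsets for tiny instances.
p = (1 + #{same-sign null at least as extreme}) / (1 + #{same-sign null});
NES divides ES by the mean same-sign null magnitude. When fewer than 10
null scores share the observed sign the p value is flagged as an upper
bound. Sample-permutation GSEA and adaptive p refinement are out of
scope. The external T_RM signature is not bundled (it lives under a GEO
accession); the package reads any GMT, and the generator emits a
synthetic `trm_demo.gmt` aligned to its planted modules.

## TCR clonotypes

Chains are collapsed per cell into sorted, deduplicated tuples of
productive α and β CDR3s. Cells with ≥ 2 productive α AND ≥ 2 productive
β chains are sorted-well doublets and removed before clone calling; cells
lacking a productive chain on either locus cannot satisfy the paired
definition and are excluded from clone statistics but counted in the
coverage report. The strict (default) clone key is the full
(α tuple, β tuple) with exact string equality — conservative and
deterministic for dual-α cells; a relaxed any-α-plus-any-β merge is
available behind a flag. Clone ids are assigned in first-seen order over
sorted cell ids, making membership input-order invariant.

Expansion is reported per (patient × compartment × timepoint) as the
fraction of paired-key cells belonging to clones of size ≥ 2 (a clone
expanded anywhere in the patient counts as expanded in every sample where
it appears; a clone-level fraction is reported alongside). Sharing lists
the compartments each clone spans; patient-axis sharing flags any clone
key found in ≥ 2 patients as public and raises a prominent warning, since
private repertoires should produce none. Persistence tabulates clones
present at both timepoints of longitudinally sampled patients with member
counts at each. The clone network is a clique per clone (s cells →
s(s−1)/2 edges, clone id on each edge), with cluster / lineage /
compartment / timepoint node attributes, exported as GraphML and an edge
list.

## Synthetic cohort

The generator emulates a 7-patient cohort (muscle + PB per patient, two
patients re-sampled after treatment → 18 samples) plus two
collagenase-digestion PB arms from a healthy donor, with:

- negative-binomial counts (dispersion 0.5) around per-cell means that
  combine a lognormal baseline program, per-cluster marker modules
  (20 genes, 2³-fold by default), CD4/CD8 lineage genes tied to alternating
  cluster lineages, a Beta(2, 40) mitochondrial fraction, lognormal
  library sizes (median ≈ 1.6M), and per-plate batch shifts (additive in
  log space, sd 0.3) on a random 10% of filler genes;
- an RPKM-like view scaling counts by per-gene lengths drawn once;
- the reserved gene families every QC gate needs (CD3, lineage,
  contaminant, hemoglobin, `MT-*`, `RPL/RPS`, TCR segment genes);
- 30 digestion-responsive genes (including CREM, FOSL2, CXCR4) up-shifted
  4-fold in dissociated muscle cells and in the treated digestion arm;
- planted offender cells per QC reason (defaults 2–4% each). Offenders are
  isolated perturbations so that each planted reason maps to an
  unambiguous gate set: `low_genes` restricts expression to ~30% of the
  non-mitochondrial genes (keeping CD3), `high_mito` draws its
  mitochondrial fraction from Beta(30, 15), `non_t_contaminant` silences
  CD3 and expresses the contaminant markers (tripping both the CD3 and
  contaminant gates), `rbc` carries a hemoglobin load of ~6% of its
  library (comfortably past the 2,500 gate across the gene-length
  distribution);
- tissue structure: the two tissue-residency clusters are depleted
  10-fold from blood, so muscle-vs-PB DE has a planted positive program;
- a clonal repertoire: expanded clones (truncated-geometric sizes, max 8)
  are drawn per patient until 35% of eligible cells belong to one —
  placing the expanded-cell fraction inside the 20–50% range typical of
  inflamed-muscle repertoires — preferring cells of the residency-biased
  clusters (weight 3), spanning both compartments with probability 0.6
  and both timepoints with probability 0.5; remaining cells get unique
  receptors; 3% of cells are 2α2β doublets; 5% carry an extra
  nonproductive chain. Offender and digestion-arm cells emit no chains
  (assembly assumed to fail on poor wells).

Everything is recorded in a ground-truth object (cluster and offender per
cell, marker and digestion gene lists, clone membership and attributes,
doublets, per-cell QC metrics), and identical configs (including seed)
produce byte-identical outputs.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: no empirical mean–variance relationship
beyond the NB family, no ambient RNA or expression-level doublets, no
read- or sequence-level realism (CDR3s are random strings, so clone
identity is purely planted), no biological correlation between marker
programs, and offender cells perturb exactly one gate family rather than
failing several at once as real degraded wells often do. Exact-recovery
results (QC, clonotypes) demonstrate the bookkeeping is correct;
statistical-recovery results (markers, ARI, GSEA p) demonstrate power
under the planted effect sizes only.

## Problem sizes and numerical choices

Test and acceptance instances are sized to be quick while keeping ≥ 500
cells wherever rate fidelity is asserted: the QC-exactness cohort uses 84
cells/sample (~1,500 patient cells), marker/clustering instances 60
cells/sample, the repertoire instance 39 cells/sample (~700 patient
cells), and the end-to-end determinism run 20 cells/sample. The
marker-recovery instance sets the batch shift to zero so planted cluster
labels are the only differential axis; false-discovery counting excludes
the CD4/CD8 lineage genes, which are genuinely differential between
lineage-assigned clusters by construction. Where Bonferroni-adjusted
muscle-vs-PB significance is required (top-50 content), instances use the
cohort-scale 84 cells/sample, since rank-sum tests have limited power for
minority-mixture composition shifts at smaller sizes.

Numerical conventions collected in one place: Wilcoxon switches to the
approximation at group size > 10 or any pooled tie; constant pooled
samples give p = 1; fold changes use pseudocount 1; PCA sign fixing and
beyond-rank zeroing as above; ES extremum ties take the earlier position;
cluster labels sort by size then first occurrence; clone ids sort by
first member cell id; all RNG flows from named seeds (numpy Generator /
seeded igraph RNG) with no global state.

## Limitations

Muscle and blood are clustered independently; no integration or label
transfer links their cluster ids. The batch adjustment removes additive
offsets only. Bonferroni is deliberately conservative; no
pseudobulk/mixed-model DE is offered, so patient-level pseudoreplication
is not modeled. GSEA p values are gene-permutation p values and inherit
that null's known anti-conservatism for correlated gene sets. Clone
identity is exact CDR3 string equality — no similarity clustering — and
cells with a missing chain are dropped from clone statistics rather than
rescued by the relaxed mode by default.
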