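# margin-profiler

Multi-stage transcriptomic profiling of infiltrative **5ALA+ glioblastoma
cells** — the residual tumor cells at the invasive margin that fluoresce
under 5-aminolevulinic acid during surgery and drive recurrence.  The
package is a tested, reusable re-implementation of the analysis chain such
a study needs, for computational biologists who want each stage as an
importable, oracle-tested function rather than a pile of one-off scripts:

| stage | module | method |
|---|---|---|
| differential expression + preranked GSEA + ssGSEA | `enrichment` | Welch/paired t + BH; weighted KS running sum, gene-label permutation NES, exact small-universe p |
| per-cell signature scores, composite signature, stemness | `signatures` | UCell (Mann–Whitney U on truncated ranks), leading-edge union with provenance, OCLR one-class regression → mRNAsi |
| bulk deconvolution | `deconvolution` | min-κ signature matrix from labeled cells; NNLS fractions on the unit simplex; High/Int/Low AUC categories; log10 program ratios |
| copy number & ploidy | `cnv` | reference-centered, clamped, moving-average CNV; Chr7+/Chr10− conjunction calls; Fisher cluster enrichment; top-k spot contrasts |
| exon–intron split analysis | `eisa` | per-channel normalization log2(x+8); transcriptional vs post-transcriptional classification |
| regulatory networks | `grn` | rank-binned mutual information, DPI triangle pruning, bootstrap consensus with an MI significance gate |
| spatial transcriptomics | `spatial` | ssGSEA/UCell spot scoring; geographically weighted local correlation (Gaussian/bi-square kernels); ENR_CT/ENR_INV segmentation |
| recurrence survival | `recurrence` | z-summed ssGSEA combined score; per-stage Spearman; Cox PH (Efron); bootstrap-balanced Wilcoxon |
| synthetic study design | `synthetic` | seeded generators for bulk compartments, single cells with planted aneuploidy, a 32×33 spot grid, survival cohorts |
| formats & types | `io_core` | TSV/MTX expression, GMT, BED-like positions, survival CSV, spot tables, YAML config |

The statistics at the core, in the field's notation: preranked GSEA scores
a set S in a ranking r by the signed extremum of
`Σ_{j≤i, j∈S} |r_j|^p / Σ_{S} |r|^p − Σ_{j≤i, j∉S} 1/(N−N_H)`,
normalized by the mean same-sign permutation ES; UCell is
`max(0, 1 − U/(n·r_max))` with U the Mann–Whitney statistic of the
signature's truncated ranks; deconvolution solves `min_{f≥0} ‖S f − b‖²`
per sample and renormalizes f to the simplex; a cell is aneuploid iff its
smoothed CNV means satisfy `chr7 ≥ +τ ∧ chr10 ≤ −τ`; geographically
weighted correlation computes a Pearson ρ per spot under kernel weights
`w_ij = exp(−d_ij²/2b²)`.

Because the original cohorts are controlled-access or large, the package
ships a first-class synthetic module that emulates the study design —
compartment-specific program activation, a 5% myeloid-like aneuploid cell
subset, 5ALA niches at the tumor boundary, and a score–survival coupling
present only in recurrent disease.  Generators return ground truth that no
analysis stage reads; the test suite measures recovery of that truth.  See
`docs/methods.md` for models, defaults and limitations.

## Worked example

`examples/` holds one short script per capability.  The enrichment example
contrasts the 5ALA+ compartment against all other regions and runs
preranked GSEA over the ten planted programs:

```bash
$ python examples/bulk_enrichment.py
program           NES     padj  leading edge
TNF              2.50   0.0022  30/30 genes
InfWound         2.49   0.0022  30/30 genes
InfResponse      2.45   0.0022  30/30 genes
MES              2.44   0.0022  30/30 genes
MTC              2.43   0.0022  30/30 genes
GPM              2.42   0.0022  30/30 genes
Hypoxia         -2.02   0.0088  24/30 genes
Developmental   -2.44   0.0055  23/30 genes
Proliferation   -2.84   0.0055  28/30 genes
Neuronal        -2.96   0.0055  25/30 genes
```

The six programs planted as active in 5ALA+ cells come out with positive
NES at padj < 0.01 and full leading edges; the compartment programs planted
elsewhere (hypoxic/stem-like core, proliferative rim, neuronal background)
are symmetrically depleted.  Chaining into
`examples/composite_signature.py` unions those leading edges into a
180-gene composite signature that recovers 180/180 planted program genes.
The spatial example prints the margin phenotype directly:

```bash
$ python examples/spatial_colocalization.py
median local rho inside 5ALA niche 0.69 vs outside 0.28
chr7: mean difference +0.31, p = 6.86e-18
chr10: mean difference -0.31, p = 6.86e-18
segmentation: 14 ENR_CT, 43 ENR_INV (threshold 0.279)
```

— the 5ALA and immune programs co-localize only inside the planted niches,
and the top-scoring spots carry the Chr7-gain/Chr10-loss tumor karyotype
relative to non-tumor tissue, splitting into a tumor-interior pocket and an
invasive-margin arc.

The same chains run on user data via the `io_core` readers
(`read_expression_matrix`, `read_gmt`, `read_position_table`,
`read_spot_table`, `read_survival_table`).

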