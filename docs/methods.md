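# Methods

`margin_profiler` re-implements, as one tested library, the computational
stages used to characterize infiltrative 5ALA-fluorescent (5ALA+)
glioblastoma cells: program enrichment in regional bulk profiles,
construction of a composite 5ALA+ signature, cell-fraction deconvolution,
expression-inferred ploidy, exon–intron split analysis, mutual-information
network inference, stemness indexing, spatial co-localization, and
score–survival analysis in primary versus recurrent disease.  Every stage
runs end-to-end on seeded synthetic data that emulates the study design, so
each claim the test suite makes is a claim about recovery of *planted*
structure, not about real tissue.

## Enrichment statistics

**Differential expression.** Per-gene two-group contrasts on log2(TPM+1)
use Welch's t (or a paired t for patient-matched designs) with
Benjamini–Hochberg adjustment across all tested genes.  Genes with no
variance are flagged and assigned p = 1 rather than an undefined statistic.
An empirical-Bayes moderated linear model would shrink per-gene variances;
the plain t keeps the stage self-contained and exactly testable against
null simulations, and at the n ≥ 10 per group used here the difference is
immaterial.

**Preranked GSEA.** For a ranked list of N genes with statistics r_j and a
set of N_H members, the running sum increments by |r_j|^p / Σ_hits |r|^p at
hits and decrements by 1/(N − N_H) at misses (weight p = 1 by default); the
enrichment score ES is the signed maximal deviation.  When the positive and
negative extrema tie in magnitude (within 1e-12), the positive one is
taken — the tie rule is part of the contract so that independent
implementations agree bitwise.  The null randomizes set membership over the
ranked universe: NES = ES / mean |null ES of matching sign|, and the
p-value is the sign-matched tail frequency (add-one smoothed when
sampling).  On universes small enough that C(N, N_H) subsets can be
enumerated (≤ 5×10^5 by default), `exact=True` switches to exhaustive
enumeration and the p-value is exact.  Ties in the ranking statistic are
broken by gene id; set-size filters default to [5, 2000].

**ssGSEA.** Per sample, genes are ranked by expression (descending, ties by
gene id) and assigned rank values N..1; the score is Σ_j (P_hit(j) −
P_miss(j)) with hits weighted by rank^α (α = 0.25).  Scores are normalized
by the global max − min of the run, so they are comparable only within a
run.  α = 0 reduces to the unweighted running-sum area, which is the form
checked against a hand-computed oracle.

## Signature scoring and construction

**UCell.** Within each cell, genes are ranked descending with average ties;
ranks beyond r_max (default 1500, the published default) are truncated to
r_max + 1.  With U the Mann–Whitney statistic of the signature ranks, the
score is clamp(1 − U/(n·r_max), 0, 1).  When every signature gene is
truncated the score floors at (n−1)/(2·r_max) — effectively zero for
realistic r_max, and exactly zero for a single-gene signature.  Being
rank-based the score is invariant under any strictly monotone transform of
a cell's expression.

**Composite signature.** Gene sets with BH-adjusted p < 0.05 and NES > 0 in
the target-vs-rest enrichment contribute their leading edges; the signature
is the de-duplicated union, gated on positive log2 fold change in the same
contrast (the gate can be disabled).  Per-gene provenance (which sets
contributed it) is retained, making the construction idempotent and
auditable.  On the default synthetic design the signature recovers the six
planted 5ALA+ programs essentially completely (180 genes).

**Stemness (OCLR / mRNAsi).** A one-class logistic regression minimizes
Σ_i softplus(−wᵀx_i) + (λ/2)‖w‖² over stem-cell profiles by full-batch
gradient descent with backtracking line search (tolerance 1e-6 on the
gradient sup-norm, ≤ 5000 iterations, deterministic start at w = 0).
Training profiles must be centered against an *external* reference cohort:
if their own per-gene means are zero, w = 0 is the unique optimum of this
convex objective and the model is vacuous — the function warns in that
case.  mRNAsi is the Spearman correlation between w and a sample's
expression over shared genes, min–max scaled to [0, 1] across the scored
cohort; it is therefore a cohort-relative index.

## Deconvolution

The signature matrix is built from labeled cells: per class, genes with
one-vs-rest Welch-t BH q < 0.3 and positive fold change are ranked by fold
change; for each G in a candidate range the top-G genes per class form a
class-mean (linear-scale) matrix, and the candidate minimizing the
condition number κ is kept.  The default range 50–150 genes/class follows
the published tool's convention for genome-scale marker pools; for the
synthetic 30-gene programs the end-to-end analyses use 20–30 genes/class —
a basis commensurate with program size (a 10-gene basis proved too small
against baseline mismatch between cell-derived signatures and bulk
profiles).

Fractions are estimated per bulk sample by non-negative least squares on
the shared-gene subspace and renormalized to the unit simplex; the residual
RMSE is reported and an all-zero solution is flagged degenerate (equal
fractions returned with a warning).  NNLS replaces the hosted tool's
ν-SVR: it preserves the estimation contract, is deterministic, and admits
exact recovery tests (noiseless mixtures recovered to 1e-6; mean absolute
error < 0.05 at noise SD 0.1).  No batch-correction step is implemented.
The Inf-wound/Developmental statistic is log10((f_a + ε)/(f_b + ε)) with
ε = 1e-3.  AUC-based High/Intermediate/Low categories use tertiles by
default (boundary values fall to the lower category) or fixed cuts.

## Copy number and ploidy

Relative copy number = per-gene log2 expression minus the reference-cell
mean, clamped to ±3, then smoothed per chromosome with a centered moving
average of 101 genes in genomic order (shrinking windows at chromosome
edges; chromosomes with fewer than window/2 matched genes are skipped).
Reference cells are an input annotation — in practice a cluster of
confidently normal cells.  A cell is aneuploid iff chr7 mean ≥ +τ AND chr10
mean ≤ −τ, the conjunction encoding the canonical glioblastoma karyotype;
τ = 0.1 was chosen so that, at the synthetic noise level, chromosome-mean
noise (SD ≈ 0.03 over ~130 genes) leaves a wide margin on both sides of the
planted ±0.5 shift.  τ is validated only on synthetic data.  Cluster
enrichment of aneuploid cells uses two-sided Fisher exact tests
(one-vs-rest), cross-product odds ratios with the Haldane–Anscombe 0.5
correction for empty cells, Woolf logit 95% CIs, and BH adjustment across
clusters.  The top-k spot contrast takes the k highest-scoring spots (ties
by spot id) against the k lowest-scoring spots of the non-tumor mask and
compares per-spot chromosome means with a two-sided Wilcoxon rank-sum test;
whole chromosomes only, no arm-level calls, no HMM states.

## Exon–intron split analysis

Exon and intron counts are normalized separately by x/L_s × mean(L) (L_s =
sample library size) and transformed as log2(x + 8); the pseudocount
follows the source method's convention.  Note the normalization removes
per-sample depth but is not invariant to a global rescaling of all
libraries.  Genes need mean log2 ≥ 5 in both channels.  Δexon and Δintron
are group-mean differences with per-channel (paired) t-tests; a gene is
*transcriptional* when the intron change is significant and concordant in
sign with the exon change, *post_transcriptional* when only the exon change
is significant and |Δexon − Δintron| > 1 log2 unit (configurable), *mixed*
when a single channel is significant without meeting either rule.
Channel-specific rankings feed the preranked GSEA for pathway-level
readout.  Read-to-gene ambiguity is an upstream exclusion, not recomputed.

## Network inference

Mutual information uses ordinal-rank transforms and exact equal-frequency
binning into ⌈n^{1/3}⌉ + 1 bins, plug-in estimation in bits.  The estimator
is exactly symmetric (canonical operand order) and returns exactly 1 bit
for a perfectly dependent binary partition; like every plug-in estimator it
carries a positive bias of ≈ (B−1)²/(2n ln 2) bits under independence,
which the tests account for explicitly.  DPI pruning scans every fully
connected triangle and marks the edge whose MI is strictly below
(1 − tolerance) × the smaller of the other two; ties remove nothing, and all
triangles are scanned before any removal.  Bootstrap consensus re-infers
the network on B resampled datasets; within each replicate, edges must
first exceed an MI significance threshold (the 1 − 10⁻³ quantile of MI
between permuted pairs, estimated under the same resampling process —
joint duplication of bootstrap pairs inflates rank-binned MI and is part of
the null).  Edge counts are then tested against Binomial(B, p̂) with p̂ the
mean edge density across replicates; edges with P(X ≥ c) < 10⁻⁴ survive.
Without the significance gate the consensus null is vacuous: the
chance-strongest edge of even independent data recurs in every replicate.
TF lists are inputs; no activation/repression sign is inferred.

## Spatial analysis

Spots live on an integer grid (0-based units; the 55 µm pitch is metadata).
Geographically weighted correlation computes, at every spot, a weighted
Pearson correlation of two score channels under a non-adaptive distance
kernel — Gaussian exp(−d²/2b²) or bi-square (1 − (d/b)²)² for d < b —
with bandwidth b = 5 grid units by default.  Local ρ is undefined (NaN)
where a weighted variance vanishes; as b → ∞ every local ρ converges to the
global Pearson correlation (asserted to 1e-9).  Co-localization matrices
summarize channel pairs by the median local ρ.  The full semi-parametric
mixed GW regression of the source workflow is deliberately reduced to these
GW summary statistics.

Segmentation thresholds a score channel and splits enriched spots by a
cellular-tumor mask: ENR_CT inside, ENR_INV outside.  The default threshold
is a robust normal fit (median, MAD-scaled) at +4σ, chosen so that a grid
with no planted niche yields no enriched spots; empirical-quantile and
fitted-quantile rules are available (`threshold=("quantile", q)` /
`("fit-quantile", q)`).  The CT mask is typically derived from chr7-gain
CNV calls on the spots; because the synthetic invasive margin carries
half-strength CNV (lower tumor purity), a purity-sensitive cutoff
(chr7 mean ≥ 0.35) separates interior from margin.

## Recurrence analysis

The combined signature score z-normalizes each contributing set's ssGSEA
score across the cohort and sums per sample (raw-sum and mean variants are
flags); it is a cohort-relative quantity centered at zero.  Score–survival
association is the Spearman correlation against overall survival, computed
separately in primary and recurrent arms.  Cox proportional-hazards models
(univariate per term, or joint) are fitted with Efron tie handling via
lifelines, reporting hazard ratios with Wald 95% CIs; multivariate fits
require ≥ 10 events.  For unequal group sizes, the bootstrap-balanced
Wilcoxon subsamples the larger group without replacement to the smaller
group's size (with-replacement is a flag), reporting the mean and [min,
max] of the per-iteration two-sided rank-sum p-values; equal sizes reduce
to the single exact test.

## Synthetic study design

The generators define the study conditions; all are bit-reproducible under
a fixed seed and return ground truth that no pipeline stage reads.

* **Bulk compartments** — 10 patients × 5 compartments (Core, Rim,
  invasive margin, 5ALA+, 5ALA−), 3000 genes of which 10 programs × 30
  genes are planted.  log2 expression = Uniform(1,7) baseline + program
  shift + per-patient gene effect N(0, 0.3) + N(0, 0.5) noise,
  back-transformed to TPM.  Default shifts: the six 5ALA+ programs (MES,
  InfWound, GPM, MTC, TNF, InfResponse) at +1 in 5ALA+; Core carries
  Hypoxia/Developmental (+1) with GPM/Proliferation (+0.5); Rim carries
  Proliferation (+1); the margin and 5ALA− fraction carry Neuronal (+1).
  Effect sizes are design choices (the source study estimates, not
  prescribes, its contrasts): +1 log2 at noise SD 0.5 and n = 10 gives the
  DE stage ~100% power per gene while keeping single-sample scores off
  ceiling.
* **Single cells** — negative-binomial counts (Gamma–Poisson, dispersion
  0.4) over eight states; per-state markers (25 genes, fold 4×) are drawn
  from chr1–chr6 only, so marker programs never contaminate the chr7/chr10
  readout.  The myeloid-like aneuploid state (5% of cells) multiplies chr7
  genes by 2^{+0.5} and chr10 genes by 2^{−0.5}; its transcriptional
  similarity to diploid myeloid cells is *not* emulated (marker sets must
  be disjoint), only the genomic contrast that defines it.  Planted cluster
  ids stand in for upstream clustering, which is out of scope.
* **Spot grid** — 32 × 33 spots: a necrotic core (globally depressed
  expression, hypoxia program), a cellular-tumor ring (proliferation), a
  two-spot-thick 5ALA arc at the CT/NT interface, a 5ALA pocket inside the
  CT, an immune-reactive rim over the remaining interface, and neuronal
  non-tumor tissue.  Tumor-bearing regions carry chr7 +0.5 / chr10 −0.5
  log2 shifts; the invasive arc carries ±0.25 — tumor cells diluted by
  normal tissue at the margin — which is what lets a purity threshold
  separate 5ALA-CT from 5ALA-INV while the arc still shows the tumor
  karyotype against NT spots.  Inside the 5ALA niches a shared per-spot
  latent factor N(0, 0.5) moves the 5ALA and immune programs together,
  planting co-localization that distance-weighted correlation can find and
  position shuffling destroys.
* **Survival cohorts** — 30 primary + 30 recurrent samples; scores and
  exponential event times (median 12 months) couple through a Gaussian
  copula at ρ = −0.9 in the recurrent arm and are independent in the
  primary arm; independent exponential censoring yields ~20% censored.

What the generators do **not** emulate: sequencing depth artifacts, batch
effects, doublets/ambient RNA, cell-type compositional autocorrelation in
space beyond the planted regions, arm-level or focal CNV, non-proportional
hazards, or cohort heterogeneity across studies.  Passing tests therefore
demonstrate correctness of the statistics and recoverability of planted
structure at realistic effect sizes — not performance on real tissue.

## Numerical and engineering choices

* Expression containers validate invariants eagerly (unique ids, finite
  non-negative values, integral counts) and name the offending record.
* GSEA ES extrema are evaluated only at the 2·N_H candidate points adjacent
  to hits, making exhaustive enumeration cheap; the positive-on-tie rule is
  shared with the test oracle.
* NNLS, Fisher exact, rank statistics, BH, and Cox fits delegate to
  scipy/statsmodels/lifelines; everything method-specific (GSEA, ssGSEA,
  UCell, OCLR, CNV smoothing, MI/DPI, EISA, GW correlation) is implemented
  here and tested against independent oracles.
* Degenerate inputs fail loudly (constant rankings, all-equal stemness
  scores, single clusters, missing chromosomes) or are flagged (constant
  genes, degenerate NNLS, undefined local ρ) rather than silently imputed.
* Problem sizes in the test suite — 2000 cells × 3000 genes for the ploidy
  chain, a 1056-spot grid, 200 cohort seeds, B = 100 bootstrap networks —
  were chosen as the smallest scales at which the planted effects are
  comfortably identifiable; the full suite runs in about a minute.

## Known limitations

* The DE stage does not shrink variances; very small groups (n < 5) lose
  power relative to moderated models.
* mRNAsi and the combined signature score are cohort-relative; scores are
  not comparable across separately scored cohorts.
* The MI estimator's plug-in bias grows with bin count; comparisons should
  stay within a fixed n (the DPI and consensus stages only ever compare
  MIs at equal n).
* The CT/margin segmentation depends on a purity-sensitive CNV threshold;
  on real spots, purity varies continuously and the boundary is fuzzier
  than the planted two-level design.
* No batch correction anywhere in the deconvolution path; signature and
  bulk data are assumed on commensurate scales.
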