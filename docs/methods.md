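# Methods

`snatlas` re-implements, as a tested library, the computational stages of a
multi-tumor single-nucleus transcriptome analysis of adrenocortical tumors:
nucleus quality control and marker detection, recurrent gene-module
(meta-program) discovery across tumors, windowed expression-based CNV
calling against a normal reference, bulk signature scoring and cell-fraction
deconvolution, ecotype construction, and survival association.  This note
documents the models, the parameters that matter, the synthetic data used
for validation, and the numerical choices made where the design was open.

## Quality control and normalization

Nuclei are removed when they have fewer than 500 or more than 8000 detected
genes (count > 0) or a mitochondrial fraction strictly above 5%
(mitochondrial genes identified by the configurable id prefix `MT-`).
Removal is strict at the printed thresholds: a nucleus with exactly 500
detected genes is kept.

Normalization scales each cell to the dataset's median depth and applies
log1p.  This is a deliberate stand-in for variance-stabilizing regression
normalization: the downstream procedures (PCA-based module extraction,
bin-matched scoring, window smoothing) need only a variance-reasonable
log-scale matrix, and the simple transform is deterministic and exactly
invertible, which the tests exploit.  Consequence worth knowing: scaling
every cell's counts by a common factor changes the median target, so the
CNV caller's output is invariant to overall sequencing depth only up to
boundary effects (the test suite asserts ≥99% call agreement under a 3×
depth change); an internal fixed-depth rescale was considered and rejected
because it distorts log-space shift semantics of the window signal.

Markers are detected per cluster versus the rest with a two-sided Wilcoxon
rank-sum test on raw counts.  Genes qualify when the log2 fold-change
log2(mean_in+1) − log2(mean_out+1) (means of depth-normalized expression)
exceeds 0.25, the difference is positive, and the gene is expressed in more
than 10% of cells of at least one of the two groups ("one group" is read as
either group, the convention of the tool family this mirrors).  Bonferroni
correction multiplies by the total number of genes in the matrix.

## Recurrent gene-module discovery

Per tumor (steroid cells only, skipping tumors with fewer than 250 cells),
PCA is computed on centered — not unit-scaled — log-normalized expression,
all nonzero-variance genes included.  Centering-only preserves
magnitude-driven programs; unit scaling would up-weight noisy low-expression
genes.  Each of the first 10 components emits two candidate modules: the 50
genes with the largest positive loadings and the 50 most negative, ties
broken lexicographically by gene id for determinism.

Candidate modules are compared with the Sørensen index 2|A∩B|/(|A|+|B|).
A module is kept only if at least 2 other modules are similar at ≥ 0.4; the
filter is applied in a single pass, not iterated to a fixed point (iteration
would silently strengthen the rule).  The kept modules are clustered by
average linkage on 1 − Sørensen.  The dendrogram cut is chosen by scanning
partitions from finest to coarsest and retaining the partition that
maximizes the number of clusters spanning ≥ 3 distinct source tumors (ties
resolved toward the finer cut); clusters failing the tumor criterion at the
chosen cut are dropped, not merged further.  This makes the cut rule fully
deterministic while honoring the ≥3-tumor recurrence criterion.  Finally,
a cluster's consensus genes are those contributed by modules from at least
50% of the cluster's tumors (inclusive; a gene present in both signed
modules of one tumor counts that tumor once).

Cells are scored per consensus module as the mean normalized expression of
the module's genes minus the mean of expression-bin-matched control genes
(25 mean-expression bins, 50 controls per module gene, drawn with a fixed
seed), and labeled with the argmax module, ties toward the smallest module
id.  The bin-matched control scheme is the standard correction for
depth/complexity-driven score inflation.

## Windowed CNV calling

Genes with mean raw count below 0.1 across all cells are removed.  The
remaining genes are ordered by genomic position; within each chromosome a
100-gene window slides by one gene (no window crosses a chromosome
boundary; chromosomes shorter than one window are skipped).  The signal of
cell c at window w is the window mean of (log-normalized expression −
reference-cell mean per gene), then centered by the cell's median window
signal.  The median centering is this implementation's addition: depth
normalization converts a focal gain into a small genome-wide negative
offset in carrier cells, which uncentered signal would miscall as losses.

Denoising flattens query signal within 1.5 standard deviations of the
pooled reference signal (mean and SD pooled over reference cells and
windows — the global convention) back to the reference mean; reference rows
are left untouched so the calling interval keeps its spread.  Calls then
compare the denoised query signal to the per-window empirical 99% interval
of the reference signal, taken at the outer order statistics so the
interval holds at least 99% of reference mass; below → loss, above → gain.
A cell is malignant when strictly more than 3% of its windows are
non-neutral.  The altered fraction is measured in window space, the
method's native resolution; base-pair weighting would require arm
annotations the procedure does not use.

A scale note: the malignancy rule is only meaningful when the genome spans
many window-lengths, because a single noise excursion perturbs up to ~100
overlapping windows.  The synthetic genome therefore uses 7,200 genes over
10 chromosomes (~6,200 windows), so 3% of windows ≈ 1.9 window-lengths —
small enough for a real 300-gene event to trip, large enough that null
cells stay below it (measured null malignancy ≈ 1–2%).

## Bulk signatures: ssGSEA and deconvolution

ssGSEA ranks a sample's genes by expression (descending, average ranks on
ties, residual ties broken by gene id) and walks the ranking accumulating
the difference between the normalized in-set weight (rank^0.25) and the
out-set count; the score is the sum of the differences over all positions.
The exponent 0.25 is the published default for this statistic.  The score
is invariant to any rank-preserving transform of expression; when the gene
set covers every gene the statistic degenerates to 0.  An optional
range-normalization across samples exists but is off by default.

Cell fractions are estimated by non-negative least squares of each bulk
profile on a signature matrix of population mean profiles (depth-normalized
counts over a marker gene space), renormalized to the simplex, with the
per-sample relative residual reported.  This is a transparent stand-in for
a proprietary hosted deconvolution service: the analysis contract
(fractions from a single-cell reference over marker genes) is preserved;
the service's batch-correction modes are out of scope.  Populations with
fewer than 50 cells are excluded from the signature matrix; near-collinear
columns trigger a condition-number warning.  Split validation samples 1000
training cells per population when the population exceeds 2000 cells,
otherwise 50%, builds the signature from the training cells, forms a
pseudobulk (summed raw counts, depth-normalized) from the held-out cells,
and reports the Pearson correlation between deconvolved and true held-out
proportions.

## Ecotypes

Signature score columns are standardized within each bulk dataset (sample
SD, ddof=1) and clamped to ±3; constant columns map to zero with a warning.
Signatures are grouped by a subsampled consensus scheme: for each k from 2
to max_k = 10, 100 resamples draw 80% of samples and cluster the signatures
(average linkage, 1 − Pearson distance); co-clustering frequencies define
the consensus matrix, which is itself clustered at k to score the partition
by mean within-cluster minus mean between-cluster consensus.  The retained
k maximizes this gap, preferring the finest partition on ties (two planted
blocks that merge perfectly at a coarser k should not absorb a finer but
equally consistent split).  The cited consensus-clustering package's
"default parameters" are not a specification; this scheme is the standard
consensus construction, fully determined here and seeded.  An ecotype's
per-sample score is exactly the sum of its member signatures' capped
Z-scores.

## Survival association

Disease-free survival is analyzed in stage I–III samples, overall survival
in stage I–IV.  Median splits assign samples exactly at the median to the
low-score group (the printed rule "> vs < median" leaves ties undefined; a
deterministic rule is required).  Continuous covariates are standardized to
unit SD before Cox fitting, so hazard ratios read per SD.  Batched
univariate Cox p-values are Benjamini–Hochberg adjusted.  The stepwise
multivariable model is backward elimination from the full model, removing
the largest Wald p ≥ 0.05 until all remaining covariates are significant;
direction and criterion are this package's choice where only "stepwise" was
specified.  Nested models are compared on identical samples by Harrell's
C-index and a likelihood-ratio test on 2·Δlog-likelihood with df = number
of added covariates.  Cox fitting, Kaplan–Meier estimation, the log-rank
test and the C-index are delegated to lifelines; exactly collinear
covariates in the nested comparison fall back to a tiny ridge penalty with
a warning so the degenerate ΔC ≈ 0 / LRT ≈ 0 case is reportable rather
than an exception.

## Synthetic data

The generator exists so that every stage has a parameter-recovery test with
known truth; its defaults are the study conditions of the test suite.

* **Counts** are negative binomial with variance mean + φ·mean², φ = 0.3,
  around log-normal per-gene baselines (log-mean −0.7, log-SD 1.0) — a
  standard droplet-style count model.
* **Programs**: module activity per cell is on/off (Bernoulli 1/2) rather
  than continuous, which makes "top-50 genes per component" recovery
  well-posed; active cells shift module-gene log-means by the effect size.
  The default multi-tumor scenario plants 3 shared programs (4 carriers of
  6 tumors; effects 2.5/2.0/1.6) and one private program per tumor (effect
  1.2).  The effects differ deliberately: equal-strength co-active programs
  make the within-tumor covariance rotationally degenerate, which no
  PCA-based method can disentangle — and real programs differ in strength.
* **CNV cells**: 10 chromosomes × 720 genes, 400 reference and 300 query
  cells; carrier cells have NB means multiplied by the event fold-change
  across the event span before sampling.
* **Bulk cohorts**: 12 signature activities in 4 correlation blocks
  (within-block r = 0.8 via shared block latents), population proportions a
  softmax of the activities, expression = proportions × signature profiles
  with 10% multiplicative log-normal noise, 3 dataset strata round-robin.
  Survival times are exponential with log-hazard linear in the standardized
  block latents; censoring is an independent exponential clock at 2/3 the
  baseline hazard rate, giving ≈40% censoring, a realistic event fraction.

What the generator does **not** emulate: ambient RNA, doublets, batch and
platform effects, cell-cycle structure, continuous (non-bimodal) program
activity, genome-position-dependent expression covariance, and
non-proportional hazards.  Passing recovery tests therefore demonstrate
correctness of the procedures under their own model assumptions, not
performance on real tumors; real-data figures of merit (e.g. a split-
validation correlation near 0.7 rather than near 1) will be worse.

## Problem sizes and determinism

Test and acceptance problem sizes — 6 tumors × 800 cells × 2,000 genes for
module discovery, 700 cells × 7,200 genes for CNV, cohorts of 200 with 100
replicates for survival calibration — were chosen as the smallest scales at
which each recovery question is statistically well-posed.  All randomness
flows through explicit seeds (NumPy Generators; replicate seeds spawned
from a root SeedSequence), and every pipeline output is deterministic given
its inputs and seed.

## Known limitations

* The SCTransform-style variance stabilization is approximated by
  median-depth log normalization (see above).
* Depth-scaling invariance of CNV calls is approximate, and the mean-count
  gene filter is depth-dependent by definition.
* The consensus-partition k-selection statistic is one reasonable choice
  among several; the assignment, not the k statistic, is the tested
  contract.
* Deconvolution is plain NNLS: no batch correction between the single-cell
  reference and bulk mixtures, which real cross-platform data would need.
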