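# Methods

## Scope and model

gwaskit implements a complete single-trait GWAS engine for quantitative
phenotypes: a file-backed genotype store, population-structure estimation
through the VanRaden genomic relationship matrix (GRM), four
variance-component estimators, and per-marker association scans by GLM,
MLM and FarmCPU, all sharing one blockwise design-matrix inversion kernel
and one GRM eigendecomposition per run.

The statistical model throughout is the standard polygenic mixed model

    y = X b + g + e,    Var(g) = sigma_g^2 K,    Var(e) = sigma_e^2 I,

with heritability h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2). The GLM is
the sigma_g^2 = 0 special case; FarmCPU replaces the polygenic term with
explicitly selected pseudo-QTN covariates.

## Genotype store

Genotypes are held markers-by-samples in a flat binary file read through
`numpy.memmap`, with JSON metadata and a tab-delimited marker map beside
it. Hard calls use one byte per genotype (sentinel 255 = missing);
fractional dosages use float32 with NaN. The store is immutable after
conversion, so any number of processes can map it concurrently and see
identical values, and reading one marker row costs O(n_samples) resident
memory however large the matrix is. Converters accept VCF (via cyvcf2),
PLINK bed/bim/fam (2-bit SNP-major layout decoded with a 256-entry lookup
table), HapMap text (11 metadata columns, two-letter or IUPAC genotype
codes) and delimited numeric matrices. Dosage coding is additive, 0/1/2
copies of the counted allele (ALT for VCF, A1 for PLINK, the second listed
allele for HapMap). Multiallelic VCF records are skipped and counted;
half-missing calls (`./1`) are treated as missing. Missing dosages are
mean-imputed per marker on the fly inside the GRM and the scans;
imputation proper is out of scope and expected upstream.

## GRM and principal components

The GRM is G = Z'Z / (2 * sum_j p_j (1 - p_j)) with Z the per-marker
dosage matrix centered by twice the counted-allele frequency, summed over
polymorphic markers; monomorphic markers contribute to neither numerator
nor denominator. A `denominator="paper"` switch drops the factor 2 for
compatibility with the unscaled variant of the formula that appears in
some write-ups. Construction streams marker blocks (default 2048 rows) so
peak memory is the n-by-n accumulator plus one block; the realized maximum
block size is recorded on the returned object for auditing.

One full symmetric eigendecomposition G = U diag(lambda) U' is computed
per pipeline run and reused three ways: PC scores (column j of the score
matrix is U_j * sqrt(lambda_j)), REML variance components, and the MLM
scan rotation. Eigenvalues below -1e-8 signal a malformed GRM and raise;
small negative values are clipped to zero. Eigenvector signs are fixed so
each vector's largest-magnitude loading is positive, making PC output
deterministic. An instrumented module counter lets the pipeline assert
the decomposition really happens exactly once.

## Variance components

All likelihood-based routes maximize the same restricted likelihood with
the total variance profiled out analytically, leaving a 1-D objective in
h^2. In the eigenbasis V is diagonal with entries h^2 lambda_i + (1 - h^2),
so each evaluation is O(n k).

* **Brent** (default): bounded Brent search on h^2 in [1e-6, 1 - 1e-6]
  with absolute tolerance 1e-6 on h^2 — convergence is judged on the
  heritability itself, not the individual components.
* **EMMAX**: 100 log-spaced grid points in delta = sigma_e^2/sigma_g^2
  over [1e-5, 1e5], then Brent refinement inside the best bracket. Same
  objective, so it agrees with the Brent route to optimizer tolerance.
* **FaST-LMM**: the spectrum is taken from the genotype matrix itself — a
  thin SVD of the scaled marker matrix when m < n (the regime the route
  exists for), the eigendecomposition of the marker kinship otherwise
  (identical nonzero spectrum). The likelihood is evaluated through the
  nonzero components plus the identity complement without forming the
  n-by-n kinship, and matches the GRM route on the same markers.
* **HE regression**: pairwise phenotype products y_i y_j (i < j, after
  residualizing on covariates and standardizing) regressed on G_ij with
  intercept; the slope, clipped to [0, 1], estimates h^2. Cheap, no
  likelihood, wider sampling error.

A flat likelihood (e.g. K proportional to I, where h^2 is unidentified up
to rescaling) returns h^2 = 0 with a `flat_likelihood` flag rather than an
arbitrary interior point. REML rather than ML is used throughout; it is
the field standard for variance components and what the EMMA and FaST-LMM
families implement.

## Association scans and the blockwise kernel

For covariate block w (intercept + covariates, fixed across markers) and
marker column x, the inverse of M = [[w'w, w'x], [x'w, x'x]] is assembled
from the once-computed (w'w)^-1 through the Schur complement
s = x'x - x'w (w'w)^-1 w'x: M22 = 1/s, M12 = -(w'w)^-1 w'x / s, M11 =
(w'w)^-1 + (w'w)^-1 w'x x'w (w'w)^-1 / s. Per marker this is a handful of
length-n dot products instead of a (k+1)-dimensional inversion. A Schur
complement at or below 1e-12 (relative to x'x) marks the marker collinear
with the covariates — monomorphic markers fall out of the same check
against the intercept — and yields missing effect/SE/p.

GLM reports the marker effect c, SE(c) = sqrt(M22 * RSS/(n-k-1)), and a
two-sided t test on n-k-1 degrees of freedom. Exact fits (RSS = 0) report
the smallest positive normal double rather than p = 0; p-values are
clamped to (0, 1]. The MLM scan implements P3D/EMMAX: variance components
are estimated once under the null, then y, the covariates and every marker
are rotated by U' and row i is scaled by 1/sqrt(h^2 lambda_i + 1 - h^2),
after which the identical blockwise machinery runs — GLS as weighted OLS.
With h^2 = 0 the transform is orthonormal and MLM output equals GLM output
exactly.

FarmCPU alternates a fixed-effect scan (GLM with the current pseudo-QTN
dosages appended as covariates; a pseudo-QTN is removed from the covariate
block when it is itself the marker under test) with pseudo-QTN reselection:
markers below the entry threshold (0.05/m, Bonferroni-informed) are ranked
by p and thinned to the best marker per genomic bin for each candidate bin
size in {5e5, 5e6, 5e7} bp (ties broken by smaller p, then lower
position); for each candidate count in {10, 20, ..., 100} capped at n/10
the leading markers form a candidate set scored by the restricted
likelihood of a random-effect model whose kinship is built from the
candidate dosages alone (evaluated through the low-rank REML route, which
is exact and cheap for q << n markers). Iteration stops when the set
repeats or after `max_loop` (default 10) passes; the report is the final
fixed-effect scan. Near-duplicate pseudo-QTNs (|r| > 0.99) are dropped
before entering the covariate block.

Scans are parallelized by partitioning markers into contiguous chunks
aligned to absolute block boundaries; each worker re-opens the shared
memory-mapped store (no copies) and writes into a preallocated result
array indexed by marker. Block alignment guarantees every marker is
processed in a block of identical shape regardless of worker count, so
result tables are bitwise identical for 1 or many workers.

The genomic inflation factor lambda_GC is the median observed chi-square
(1 df) quantile of the p-values divided by 0.4549 (the null median).

## Visualization

Manhattan (single, overlaid, stacked, circular), Q-Q with a beta
order-statistic 95% null band, marker density, phenotype distribution and
2-D/3-D PCA plots are drawn with matplotlib. Every plot function also
writes its plotted coordinate table; tests assert on the tables, never on
pixels. Cumulative genome coordinates insert an inter-chromosome gap of 1%
of the genome length; the default significance line is Bonferroni 0.05/m.
Circular tracks normalize each group's -log10(p) to its own radial band.
Foreign result tables (CHR/BP/P and similar dialects) are accepted through
a column-mapping layer.

## Simulator

`simulate_genotypes` draws ancestral frequencies uniformly from the MAF
range (default [0.05, 0.5]), lets subpopulation frequencies drift by
Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F), samples unrelated genotypes
under HWE, and builds full-sib families by Mendelian transmission from
simulated parents when `family_size > 1`. Markers are spread over 10
chromosomes of 100 Mb with uniform random positions. All randomness flows
from the explicit seed in the config.

`simulate_phenotype` places QTNs at least 2 Mb apart (so power can be
scored by locus), draws normal or equal-variance effects, and rescales the
noise — after orthogonalizing it against the genetic values — so the
realized h^2 equals the target exactly. `simulate_polygenic_from_eigen`
draws the genetic value from the GRM's own structure (g = U sqrt(lambda) z),
the correctly specified generative model for GRM-based REML, used for
parameter-recovery and structured-null studies.

What the simulator does not emulate: linkage disequilibrium and realistic
haplotype structure, genotyping error, ascertainment, case-control
liability traits, and multi-generation pedigrees. Passing tests therefore
demonstrate correctness of the estimators and scans under their own model
assumptions, not robustness to LD-driven confounding or data artifacts.

## Design choices in validation, and why

* **h^2 recovery cohorts carry relatedness** (sib families of 5). With
  n = 1000 unrelated samples and m = 10,000 markers the GRM is
  near-identity and the profiled-REML Fisher information caps any
  estimator's sampling SD near 0.13, so "recover h^2 to within 0.1" is not
  a well-posed requirement there — our estimator empirically sits on that
  information bound. In the related-cohort regime (the setting variance
  components are used in practice) median recovery error is 0.03–0.05.
* **Structured-null calibration** uses a polygenic phenotype on the
  sib-family cohort — the mixed model's own generative model — so the MLM
  should be calibrated (lambda_GC near 1) while covariate-free GLM
  inflates; this is the standard EMMAX-style design.
* **FarmCPU power studies** use two subpopulations (F_ST = 0.1) and 10
  equal-variance QTNs at h^2 = 0.3 (~3% of variance each), scored by locus
  windows: coverage within 100 kb, false positives outside 1 Mb.
* Numerical tie-breaks and degenerate inputs: covariate rank deficiency
  raises; collinear/monomorphic markers give missing statistics rather
  than exceptions mid-scan; all-missing markers get NaN frequency and are
  excluded from the GRM.

## Problem sizes used in the shipped checks

The test suite runs the oracle and calibration studies at n up to 1000 and
m up to 50,000 with 10–20 replicates where medians are asserted.
`scripts/acceptance.py` recomputes the same quantities end-to-end with 3–5
replicates per stochastic study; these are the package's reporting sizes,
chosen so a complete from-scratch reproduction stays fast on a single CPU
while leaving the asserted medians' margins intact.

## Known limitations

Single trait, quantitative phenotypes only; no logistic model, no
dominance or epistasis terms, no compressed-MLM/SUPER variants, no
imputation or QC filtering (deferred to upstream tools), no distributed
execution. The FarmCPU bin-size and count grids follow the original
method's conventions and are configuration-exposed rather than tuned.
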