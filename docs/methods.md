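# Methods

`confoundr` implements a confounder-aware differential-expression analysis
for bulk RNA-seq cohorts in which a continuous symptom score (the PCL-M,
range 17–85) is the trait of interest and some subjects contribute repeated
blood draws. This note records the statistical models, the defaults and why
they were chosen, what the synthetic cohorts do and do not emulate, and the
numerical choices that affect results.

## Low-count filtering (q35)

For each gene the 75th percentile of raw counts across samples is computed;
q35 is the 35% quantile of the resulting per-gene distribution; genes whose
75th percentile is *strictly below* q35 are discarded (a gene exactly at the
threshold is kept). Both quantiles use linear interpolation between order
statistics (R's default, type 7). The interpolation rule is a choice — the
filter is conventionally computed in R — and a different rule shifts the
kept-gene count by a handful of genes at transcriptome scale.

## Normalization

* **TMM** factors (used as offsets in all count models): reference sample =
  the one whose depth-scaled 75th percentile is closest to the sample mean;
  per-sample log2 ratios (M) and average abundances (A) over genes nonzero
  in both samples; 30% two-sided trim on M, 5% on A; weights = inverse
  asymptotic binomial variances; factors rescaled to geometric mean 1 so
  effective library sizes stay on the raw-depth scale. These are the
  published method's constants; the implementation agrees with
  edgeR::calcNormFactors to 1e-9 on test matrices. Note the weighted
  estimator is only *approximately* invariant to rescaling a single column
  (the 1/count terms in the weights are depth-dependent); the unweighted
  trimmed mean would be exactly invariant.
* **Median-of-ratios size factors** (used only to normalize counts before
  PCA): per sample, exp(median(log count − log geometric-mean reference))
  over genes expressed in every sample. The log-scale median matches the
  DESeq convention; at even gene counts it differs microscopically from a
  plain ratio median (geometric vs arithmetic mean of the two middle
  ratios).
* **RPKM** = count / (length/1e3) / (effective library/1e6); exploratory
  output only, never used for testing.

## Covariate selection

1. **PCA input**: size-factor-normalized counts, log2(x+1), genes centered,
   samples as observations. The log transform is a design choice: PCA on
   normalized counts without it is dominated by a handful of high-count
   genes. `log=False` reproduces the literal "normalized counts" reading.
2. **Number of informative PCs** by parallel analysis: each of 5 replicates
   permutes every gene's *raw* counts independently across samples, then
   recomputes size factors and the transform before PCA. k is the largest
   value (capped at 10) such that every real eigenvalue up to rank k
   strictly exceeds the maximum of the corresponding permuted eigenvalues.
   Permuting raw counts rather than the already-normalized matrix matters:
   permutation smears depth variation (which normalization removes from the
   real matrix) into every gene row, so permuted eigenvalues stochastically
   dominate under a structureless null and k=0 is returned with high
   probability. Had the *normalized* matrix been permuted, the real data
   would be exchangeable with its own permutations under the null and the
   first real eigenvalue would exceed all 5 permuted ones with probability
   1/6 — a 17% false-structure rate by construction.
3. **Screening**: each covariate against each of the k PC score vectors —
   two-sided Mann-Whitney-Wilcoxon for binary covariates (exact enumeration
   for ≤50 untied observations, normal approximation with tie correction
   otherwise), Spearman correlation for continuous, one-way ANOVA for
   categorical. Candidates: p < 0.1. The trait itself is screened for
   reporting but is never eligible as a nuisance covariate.
4. **Greedy stepdown**: per PC, candidates are offered in ascending screen
   p-value (ties broken by covariate file order, for determinism) to an
   incremental Gaussian linear model of the PC scores; a candidate is kept
   iff the nested-model likelihood-ratio test (chi-square, df = columns
   added; categorical covariates enter as full dummy blocks) has p < 0.001.
   A kept covariate absorbs its correlates' signal, so redundant candidates
   offered later fail the test. Additions that make the design
   rank-deficient are rejected and logged.
5. **Pruning**: the union of per-PC selections is visited in order of best
   screen p-value; a covariate is dropped if its association with an
   already-retained one exceeds 0.8 — |Spearman| for continuous pairs,
   Cramér's V when both are categorical, and the correlation ratio (square
   root of the one-way ANOVA R²) for mixed pairs, which the two stated
   rules do not cover. The 0.8 threshold quantifies "highly correlated" and
   is exposed in config.

## Differential expression (one measurement per subject)

For each subject the measurement with the highest PCL-M score is kept (ties:
earliest collection index, then file order); with the emulated 58/21/6
design this reduces 118 measurements to 85. The trait is coded either as the
raw score (continuous; reported fold-changes are per PCL-M point and
therefore hover near 1) or dichotomized at 34 (control < 34 ≤ symptoms).

Each gene is fit by an NB2 log-linear model: log mu = X beta + log(library
size × TMM factor). Coefficients are estimated by Fisher-scoring IRLS; the
gene-wise dispersion alpha maximizes the Cox-Reid adjusted profile
likelihood, ll(alpha) − ½ log|XᵀWX|, on the full design. Plain ML (the
`dispersion_method="ml"` option, alternating IRLS with a bounded univariate
search) is biased low in proportion to the number of fitted coefficients —
at n = 85 with seven covariates enough to push the type-I error of the LRT
visibly above nominal — which is why the adjusted likelihood is the
default; no empirical-Bayes shrinkage toward a trend is applied, and an
exact replication of shrinkage-based tools is a non-goal. Inference on the
trait is a likelihood-ratio chi-square test with the dispersion held at its
full-model estimate, as is standard for count-model DE. Genes that are all
zero, or whose fits fail, propagate as NA rows and are excluded from FDR
denominators; rows with a missing value in any selected covariate are
dropped per run and logged.

**FDR**: Benjamini-Hochberg step-up, genome-wide over converged genes, plus
one restricted column per supplied gene set in which the adjustment is
applied to member genes only (non-members NA). Restricting the denominator
is what improves the q-values of a priori plausible genes; matching is by
exact case-sensitive string identity.

## Repeated-measures mixed model

Candidate genes (single-measurement continuous-model p < 0.05, strict) are
refit on *all* measurements with a per-subject random intercept:
y_ij ~ NB(mu_ij, alpha), log mu_ij = x_ijᵀβ + offset_ij + b_i,
b_i ~ N(0, σ_u²). The marginal likelihood integrates b_i out by adaptive
Gauss-Hermite quadrature (default 8 nodes; at most 3 measurements per
subject the adaptive grid around the per-subject posterior mode makes more
nodes essentially free). Fitting profiles (β, b) at their joint mode via
penalized IRLS — the penalized weighted least-squares step is solved
through the Schur complement of the diagonal random-effect block — and
searches (log σ_u, log α) by bounded Nelder-Mead; the objective is a
deterministic function of the variance parameters (PIRLS always restarts
from the GLM fit), which the simplex contraction test requires. p-values
are LRTs on the trait coefficient. σ_u = 0 lies inside the parameter space:
the marginal likelihood then collapses exactly to the fixed-effect GLM
likelihood (verified to 1e-6), and fits whose optimum lands at the boundary
are reported with the exact GLM solution. Cohorts with no repeated subjects
are flagged degenerate and fall back to the GLM. Because the ML estimate of
σ_u under a σ_u = 0 truth is half-normal around the boundary, individual
genes can legitimately return σ̂_u > 0 with slightly shifted coefficients;
equivalence with the GLM holds in the mean across genes (~1e-4), not gene
by gene.

The discordance report lists genes whose single-measurement and mixed-model
p-values differ by more than a factor of 10 (|log10 ratio| > 1, config).

## Synthetic cohorts

The generator emulates the study design every stage is tested against:

* 85 subjects, 58/21/6 with one/two/three measurements (118 total).
* Subject peak PCL-M drawn from a two-component truncated-normal mixture —
  control N(22.7, 4.5²) on [17, 34), symptoms N(47.2, 10.3²) on [34, 85] —
  with P(symptoms) = 27/85, so the expected group split matches the cohort
  the design mimics. Non-peak measurements subtract |N(0, 3)| jitter, so the
  per-subject maximum is the generative trait and max-score selection
  recovers the planted effect exactly.
* Covariates: a 4-level aggregate batch (subject-level), log-normal blood
  counts (neutrophils, WBC; subject-level), logit-normal sequencing-QC
  percentages (GC%, mapped%, non-exonic%, de-duplicated%;
  measurement-level), plus optional standard-normal decoys. Each confounder
  affects a configured subset of genes with loadings ~ N(0, effect SD);
  categorical levels each carry their own iid effect (no reference level is
  special — only contrasts are identifiable). Defaults: batch affects all
  genes at SD 0.15; each continuous covariate affects 20% of genes at SD
  0.15–0.2.
* Confounding: one covariate's subject-level value can be tied to the trait
  (continuous: correlation rho with the standardized peak score;
  categorical: with probability rho the batch is determined by group).
  Default 0 — clean and confounded regimes are one flag apart.
* Counts: NB with gene-wise dispersion (default 0.1) around
  exp(baseline + batch + loadings·z + trait effect + b_gi + log depth),
  library sizes log-normal around 2e7. Baseline log-means are N(log 50, 1),
  giving the dynamic range the q35 filter needs to bite (roughly a third of
  genes drop at default settings).
* Random intercepts b_gi ~ N(0, σ_u²) are drawn **per gene and subject**
  (default σ_u 0.5): a subject effect shared by all genes would be
  indistinguishable from sequencing depth and absorbed by the library-size
  offset, leaving nothing for the mixed model to estimate.

What the generator does *not* emulate: gene-gene correlation beyond shared
covariate loadings, count-level zero inflation, isoform structure,
gene-length/GC dependence of counts, and missing covariate values (missing
cells can be injected manually; the fit path drops and logs them). Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated generative model, not robustness to everything real data does.

One consequence documented here because it shapes the validation suites:
with a single measurement per subject, the per-gene subject intercept is
just extra log-normal observation noise on top of NB, a family the NB
likelihood cannot represent; under that misspecification the nominal-5%
LRT rejects ~7% of null genes regardless of implementation. Type-I
calibration is therefore checked on NB-distributed nulls (σ_u = 0), and
the σ_u > 0 misspecification effect is a known limitation of
single-measurement count-model analyses generally.

## Validation studies and problem sizes

`confoundr.validation` (driven by `scripts/acceptance.py` and the
acceptance tests) uses these sizes, chosen to estimate each rate to well
under its decision margin while keeping a full run in minutes:

* type-I calibration and confounding rescue: 3 cohorts × 2,000 genes
  (≈1,300 tested after filtering), pooled;
* covariate recovery: 50 cohorts of 600 genes, 3 planted confounders
  (each affecting a quarter of genes at SD 0.3) among 20 candidates;
* parallel analysis: 50 null and 50 planted-structure cohorts of
  200 genes × 40 samples;
* mixed model: σ_u ladder {0, 0.25, 0.5, 1.0} at 50–100 genes per rung,
  GLM-equivalence at 30–50 genes.

## Numerical choices

* IRLS convergence: relative log-likelihood change < 1e-10, max 50
  iterations; dispersion search bounded on log alpha ∈ [log 1e-8, log 100]
  with a Poisson boundary check.
* Mixed model: Nelder-Mead xatol 2e-3 / fatol 1e-5 on the log scale (the
  LRT needs the log-likelihood to ~1e-3 at most), one retry with doubled
  quadrature nodes on failure; σ_u below 2e-4 reported as 0.
* BH is computed in-package (the restricted variant needs the same code
  path); it matches statsmodels' `fdr_bh` to 1e-10 in tests.
* Results are written at 12 significant digits; read-back reproduces values
  to that precision.
* All randomness flows through explicit integer seeds; permutation PCA,
  the generator and every validation study are deterministic given theirs.

## Known limitations

* Dispersion is estimated gene by gene with no information sharing; at 85
  samples this is adequate for calibration but less powerful than
  trend-shrinkage estimators for small cohorts.
* The quadrature-based mixed model supports a single random intercept only
  (no random slopes, no crossed effects, no zero inflation).
* Quantile conventions, the eigenvalue-comparison rule and the pruning
  threshold are documented choices where the procedure is conventionally
  under-specified; alternatives are exposed as parameters rather than
  hidden.
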