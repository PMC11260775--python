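# Methods

## Model and assumptions

Two-sample Mendelian randomization treats each SNP *j* as an instrument
for a modifiable exposure. The exposure association γⱼ (SD units per
allele, standard error σ_Xⱼ) and the outcome association Γⱼ (log-odds per
allele, σ_Yⱼ) come from two non-overlapping GWAS. Under the
instrumental-variable assumptions — relevance (γⱼ ≠ 0), independence from
confounders, and no direct path to the outcome (no horizontal
pleiotropy) — the per-SNP Wald ratio θⱼ = Γⱼ/γⱼ identifies the causal
log-odds of the outcome per 1 SD of exposure. Violations enter the model
as a direct effect δⱼ, so that Γⱼ = θγⱼ + δⱼ; the four estimators differ
in what they assume about the δⱼ:

| method | consistent when | key quantity |
|---|---|---|
| IVW | all δⱼ = 0 | precision-weighted mean of θ̂ⱼ, weights wⱼ = γ̂ⱼ²/σ_Yⱼ² |
| MR-Egger | InSIDE: δⱼ ⫫ γⱼ | slope of Γ̂ⱼ on γ̂ⱼ with intercept = mean δ |
| weighted median | >50% of weight valid | weighted 0.5-quantile of θ̂ⱼ |
| weighted mode | largest θ-cluster valid | weighted KDE argmax of θ̂ⱼ |

Estimates are reported as log-OR with normal-approximation 95% CIs
(β ± z₀.₉₇₅·SE) and exponentiated odds ratios.

### Standard errors

* Wald ratio: first-order delta method, SE = σ_Y/|γ| (the second-order
  term is negligible at the instrument strengths this pipeline accepts).
* IVW: fixed-effect SE (Σwⱼ)^(−1/2), multiplied under the default
  multiplicative random-effects model by max(1, √(Q/(J−1))) so
  heterogeneity widens the interval but can never narrow it.
* MR-Egger: weighted least squares with weights σ_Yⱼ⁻²; instruments are
  first oriented so γ̂ⱼ > 0 (the frame in which the intercept estimates
  mean directional pleiotropy); SEs carry the analogous max(1, √(Q'/(J−2)))
  scaling from the residual heterogeneity.
* Weighted median and mode: parametric bootstrap — γ*ⱼ ~ N(γ̂ⱼ, σ_Xⱼ²),
  Γ*ⱼ ~ N(Γ̂ⱼ, σ_Yⱼ²), estimator recomputed per replicate, SE = SD over
  replicates (default 1,000; seeds are mandatory).

### Weighted median and mode details

The weighted median sorts θ̂ⱼ, assigns plotting positions
pⱼ = Sⱼ − wⱼ/2 (Sⱼ the running normalized weight sum) and linearly
interpolates at p = 0.5. The weighted mode smooths the ratio estimates
with a Gaussian kernel of bandwidth h = φ · 0.9 · min(sd, 1.4826·MAD) ·
J^(−1/5) (φ = 1 by default, exposed in configuration; a zero MAD falls
back to the SD, and identical ratios return the common value). The argmax
is located on a 512-point grid spanning the ratio range ±2h and refined
on a local 64-point grid; the discretization error is far below h.

A known finite-sample property worth stating: with a fixed fraction of
invalid instruments all biased in one direction, the weighted median
converges not to a biased limit (as IVW does) but to a quantile of the
*valid* ratio distribution slightly off its center — a shift of order one
ratio-SE that disappears as the source GWAS grow. The robustness tests
assert exactly this behaviour: attenuation at realistic sample sizes and
convergence to the truth as the studies are scaled up, while the IVW bias
plateaus.

## Sensitivity analyses

* **Cochran's Q** over ratio estimates, χ²(J−1) under homogeneity.
* **Egger intercept** two-sided test at α = 0.05.
* **MR-PRESSO**: observed RSS = Σⱼ(Γ̂ⱼ − θ̂₍₋ⱼ₎γ̂ⱼ)² with leave-one-out
  IVW slopes; the null distribution is rebuilt by parametric simulation
  (default 1,000 draws), giving a global empirical p; per-SNP squared
  residuals against their simulated tails, Bonferroni-adjusted, flag
  outliers (note the empirical floor J/(n_sim+1): the simulation count
  must out-resolve the adjusted threshold); the distortion test compares
  the percent change in the IVW estimate after outlier removal with the
  same quantity for random same-sized subsets of non-outliers.
* **Leave-one-out** IVW per instrument.
* **Trait-category runs**: instruments annotated with a category (lipid,
  blood, inflammation, body composition, type-2-diabetes, other — the
  vocabulary is configurable) are excluded, or alternatively the analysis
  is restricted to them (keep-only mode); each run re-executes the main
  estimator battery on the reduced panel through the same code path. A
  separate run excludes proxy-substituted instruments.

## Instrument processing

**Clumping** is greedy and p-ordered: the smallest-p SNP becomes an index
and removes same-chromosome SNPs within ±window whose r² with it exceeds
the threshold; ties on p break by position, then rsid (a convention this
package fixes; upstream tools do not document theirs). SNPs absent from
the reference panel are conservatively dropped by default (configurable
to "treat as unlinked"). r² is the squared Pearson correlation of
unphased allele dosages.

**Proxy search** returns the candidate with maximal r² ≥ 0.8, ties broken
by genomic distance then rsid. The proxy's outcome effect is transported
to the target through the sign of the dosage correlation and restated on
the exposure's alleles, so a synthesized record harmonizes like a
directly measured one.

**Harmonization** never alters the exposure orientation (this keeps the
Egger orientation step well-defined). Outcome records are swapped
(negated β, reflected EAF) and/or strand-complemented as needed.
Palindromic SNPs are oriented from allele frequencies only when MAF < 0.3
in both studies — the candidate alignment with concordant frequencies
(both EAF < 0.5 or both > 0.5) is chosen — and dropped as ambiguous
otherwise; missing frequencies drop with their own audit tag. The audit
trail satisfies input = kept + dropped by construction.

**Instrument strength.** Per-SNP variance explained is 2β²x(1−x) with x
the MAF (the default "standard" formula); the variant without the factor
2, sometimes quoted in applied work, is available as `as_printed`. The
joint F is (R²/k)/((1−R²)/(n−k−1)). At R² = 0.102, n = 114,999, k = 42
this gives F ≈ 310.9 — far above the weak-instrument rule of thumb of 10.

## Power

The IVW estimate of the causal log-OR is treated as normal with SE
1/√(n·R²·K(1−K)) for outcome sample size n and case fraction K. The
two-sided test's non-centrality is |log OR|·√(n·R²·K(1−K)) and

power = Φ(ncp − z₁₋α/₂) + Φ(−ncp − z₁₋α/₂),

exactly α at OR = 1 and strictly increasing in |log OR|, n and R². The
inverse query (smallest OR detectable at a target power) is solved by
bracketed root finding. The tests validate the formula against a
Monte-Carlo oracle that simulates the full two-sample estimation at the
configured scale; agreement is within ~0.01 across the OR grid.

## Synthetic-data generator

The generator instantiates the causal diagram directly at the
summary-statistic level. Per SNP: MAF x ~ U(0.05, 0.5); true γ from
N(0, 0.08²) truncated at |γ| ≥ 0.01 (about the strength spread of
metabolite-GWAS instruments; ~50 such SNPs explain roughly 10% of
exposure variance); σ_X = 1/√(2·n_X·x(1−x)); σ_Y = 1/√(2·n_eff·x(1−x))
with the effective case-control size n_eff = 4/(1/n_case + 1/n_control);
observed effects are truth plus normal noise at these SEs, p-values from
the normal approximation. Default sample sizes are 114,999 (exposure) and
9,358/15,482 (outcome cases/controls). Pleiotropy assigns δ ~ N(μ_p, σ_p²)
to a configured fraction of instruments, applied **relative to the
exposure-increasing allele** — the frame in which the Egger intercept
estimates μ_p; a balanced flag forces μ_p = 0. LD panels are genotype
matrices (default 500 individuals) built by copy-with-mutation within
blocks so the expected within-block dosage r² hits the requested value;
distinct blocks sit farther apart than the clumping window. Requested
fractions of palindromic allele pairs, swapped outcome records, and
strand-recoded outcome records exercise every harmonization branch. All
randomness flows from one seed.

What the generator does **not** emulate: individual-level genotypes
linked to phenotypes (no linkage between panel genotypes and effect
sizes beyond block structure), sample overlap between the two studies,
MAF-dependent effect-size architecture, imputation uncertainty, and
winner's-curse inflation of the selected instruments' γ̂. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data artefacts. The binary
σ_Y convention above is the package's fixed convention; because the
generator draws noise with exactly the σ it reports, estimator
calibration results are invariant to the convention's absolute scale.

A deterministic accounting fixture complements the stochastic generator:
52 genome-wide-significant, mutually unlinked index SNPs (plus clumpable
satellites and sub-threshold SNPs), four missing from the outcome study
of which two are recoverable through planted proxies (one in anti-phase,
exercising the allele mapping), seven ambiguous palindromes and one
incompatible-allele SNP — leaving exactly 42 instruments. Its per-SNP
instrument z-scores are drawn from U(10, 20) so the total variance
explained lands near the ~10% a strong metabolite instrument set
exhibits, and mild balanced heterogeneity (δ ~ N(0, 3σ_Y)) gives the
sensitivity battery something to detect.

## Numerical choices and degenerate inputs

* CIs use z = Φ⁻¹(0.975) ≈ 1.959964, not the rounded 1.96.
* IVW with one SNP reduces exactly to the Wald ratio; random-effects
  scaling needs J ≥ 2; Egger, median and mode need J ≥ 3; MR-PRESSO
  needs J ≥ 4. Methods below their minimum are reported as absent with
  the reason; the pipeline never fails on that account.
* γ̂ = 0 raises an explicit division-by-zero error naming the rsid;
  bootstrap replicates drop zero draws of γ*.
* Exactly collinear Egger designs (all γ̂ equal after orientation) fit
  via pseudo-inverse and attach a warning to the estimate.
* Monomorphic panel SNPs raise an undefined-LD error; missing panel SNPs
  follow the configured clumping policy.
* All output tables are written with fixed float formatting, so reruns
  with identical inputs and seeds are byte-identical.

## Problem sizes used in the test and acceptance suites

Closed-form oracles run on 2–4 SNP examples. Recovery and coverage use
200 replicates (tests) / 300 replicates (acceptance script) of 100
instruments; Q calibration uses 1,000 null replicates of 50 instruments;
MR-PRESSO specificity uses 150–200 null replicates at 500–1,000
simulations each; the power oracle uses 4,000 Monte-Carlo replicates per
OR grid point. These sizes put Monte-Carlo error well inside each
assertion's tolerance while keeping the full suite under a few minutes
on one core.
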