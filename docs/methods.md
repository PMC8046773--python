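# Methods

## Scores

For subject `i` with effect-allele dosages `c_ij ∈ {0,1,2}` at the L = 11
panel SNPs and configured per-allele LTL effects `w_j` (bp):

- unweighted `U_i = Σ_j c_ij`, weighted `W_i = Σ_j c_ij w_j`. Both are defined
  only for subjects with all L calls (the "100% call rate" stratum), matching
  the convention that a missing call makes the absolute score incomparable.
- scaled variants divide the same sums, taken over the non-missing SNPs, by
  the number of non-missing SNPs: a per-SNP mean. For complete data the scaled
  score is exactly the raw score / L, hence order-identical; subjects with
  zero calls are excluded with a logged count. "Average value" is the simplest
  reading that makes incomplete subjects comparable; an 11-SNP-equivalent
  rescale (×L) would be monotone-identical and is therefore not duplicated.

### Quintiles

Cutpoint k (k = 1..4) is the smallest reference value whose empirical CDF
reaches k/5; assignment is `1 + #{cutpoints < score}`, so ties land in the
lower quintile. Teloscores are heavily tied small integers; splitting ties
would allocate subjects with identical scores to different quintiles, and the
published analysis's unequal quintile sizes show ties were kept together.
Reference strata: controls for the risk analysis; cases with complete stage,
therapy and follow-up for survival (recomputed per stage system, since DS- and
ISS-complete strata differ). Raw-variant quintiles additionally require the
reference subject to have complete calls. If a reference stratum has fewer
than five usable values (e.g. extreme missingness emptying the complete-call
stratum) that variant's quintiles are skipped with a warning and the scaled
variants proceed.

## Association models

- Risk: maximum-likelihood logistic regression (statsmodels, Newton, tol 1e-8,
  max 100 iterations; non-convergence is an error, never a silent estimate).
  Covariates: age (years; at diagnosis for cases, at recruitment for
  controls — a single column), sex, and country as reference-coded indicators
  (reference = first category alphabetically; p-values are invariant to the
  reference). SNP exposure codings: allelic = minor-allele dosage (effects
  reported per rare allele, the common-vs-rare contrast), codominant =
  heterozygote and rare-homozygote indicators vs the common homozygote (the
  hom term is dropped with a warning when no rare homozygotes exist). Score
  codings: quintile indicators Q2–Q5 vs Q1, and the quintile index 1–5 as a
  numeric trend. The per-SNP scan stamps the Bonferroni level α/(2L) = 0.0023.
- Survival: Cox proportional hazards by Newton-Raphson on the partial
  likelihood, implemented in-package with Breslow tie handling by default
  (follow-up is reported in months, so ties are common) and Efron as an
  option; log-likelihood tolerance 1e-8, max 100 iterations, step-halving,
  with monotone-likelihood detection surfacing as an explicit convergence
  error. Validated in the test suite against scikit-survival (Breslow) and
  lifelines (Efron) to ≤1e-5 and against a closed-form three-subject partial
  likelihood to 1e-6. The in-package implementation exists because the tie
  method is a modelling choice here and the calibration studies need ~10³
  fits (≈8 ms each).
- All intervals and p-values are Wald (est ± 1.96·se on the log scale),
  matching the OR/HR + 95% CI + p reporting convention.

## Mendelian randomization

Inputs are per-SNP summary pairs: `bx_j` (LTL per long-telomere allele; kb by
convention in this package — the unit is declared, not assumed) with `bxse_j`,
and `by_j` (log-OR for risk, log-HR for survival) with `byse_j`. When
assembled from association tables reported per minor allele, effects are
re-oriented to the long-telomere allele; joint sign flips leave every
estimator invariant. `byse` is recovered from printed CIs as
`(ln hi − ln lo)/3.92`; rounding of printed ORs/CIs limits downstream
agreement to roughly two significant figures.

- IVW: weighted regression of `by` on `bx` through the origin, weights
  `byse⁻²`. Fixed-effect se `(Σ w bx²)^{-1/2}`; multiplicative-random-effects
  se multiplies by `max(1, √(Q/(K−1)))`. Both are reported side by side; the
  slope is identical.
- MR-Egger: the same weighted regression with an intercept, after orienting
  all `bx_j ≥ 0` (the standard formulation; the orientation fixes the
  intercept's sign convention). SEs inflated by `max(1, √(Q_egger/(K−2)))`.
  Requires K ≥ 3 and non-constant `bx`.
- Cochran's Q with df = K−1 (IVW) or K−2 (Egger); χ² upper-tail p.
- Bowden's I²GX = max(0, (Q_GX − (K−1))/Q_GX) from (bx, bxse), truncated at
  zero with a weak-instrument warning when Q_GX = 0. Because published I²GX
  values sometimes differ between outcomes for identical instruments, the
  report also carries the outcome-weighted variant computed on
  (bx/byse, bxse/byse), labelled separately.
- Exposure-side error is ignored in point estimates and Wald-ratio SEs
  (standard first-order two-sample practice); I²GX is the diagnostic for the
  resulting dilution risk in Egger.

### Non-collapsibility

Odds and hazard ratios are non-collapsible: with a logistic liability for case
status, the per-SNP *marginal* log-ORs are attenuated relative to the
conditional log-odds per kb (θ). At the default θ = 1.175/kb and TL sd
≈ 0.96 kb the attenuation is ≈0.8, so the IVW estimand — and what real
summary-statistic MR of a binary outcome estimates — is the *marginal* causal
slope, not θ. The calibration tests therefore check IVW coverage against that
marginal slope, computed by running the generator at n = 2,000,000; θ itself
is recovered by the logistic fit on telomere length directly. At small θ
(≲0.2/kb) the two coincide to <1%.

## Synthetic cohort generator

Generative model (defaults in parentheses):

- genotypes: `c_ij ~ Binomial(2, f_j)` independent across SNPs and subjects —
  HWE, no LD (the panel spans distinct chromosomes); effect-allele frequencies
  from the panel's published control MAFs.
- telomere length: `TL_i = baseline (5500 bp) + W_i + ε`, ε normal with
  variance set from the *realized* score variance so the score explains
  `target_score_r2` (0.0228) of TL variance.
- case status: `P(case) = expit(α₀ + θ·TL_kb,centered + covariate terms)`,
  θ = 1.175 log-odds/kb (the scale of the published causal estimate), α₀
  root-solved so the expected case fraction equals `n_cases/(n_cases +
  n_controls)` (2407/4148). Covariate effects (age, sex) and per-SNP direct
  (pleiotropic) outcome effects default to zero — confounding and pleiotropy
  are opt-in.
- survival (cases): Weibull proportional hazards, shape 1.2, scale 128 months
  at the reference level, log-hazard `γ·TL_kb,centered` (γ = −0.44/kb) plus
  stage (0/0.35/0.70 by DS stage) and therapy (−0.40 for "new"-class first
  line) terms; independent exponential censoring (mean 45 months) capped
  administratively at 120 months. The scale/censoring defaults were set once
  so that ≈29% of followed cases are deceased, the published follow-up margin.
- stages: DS and ISS are cuts of two latent severities correlated at 0.6, at
  the published stage-distribution quantiles; availability masks (DS 1235/2407,
  ISS conditional on DS so that 984 cases carry both, follow-up 1273/2407,
  therapy 0.9) are MCAR.
- covariates: age ~ Normal(57, 11) years clipped to [25, 92] (between the
  published case and control medians — with no age effect the margins
  coincide), sex male 0.53, country at the published combined proportions.
- missingness: each call independently missing at 0.037, matching the 96.3%
  mean call rate; the expected complete-call fraction is (1−0.037)¹¹ ≈ 0.66.

All randomness flows from one `numpy.random.default_rng(seed)`; fixed seeds
give byte-identical outputs.

What the generator does **not** emulate: linkage disequilibrium, population
stratification or country-specific allele frequencies, informative (non-MCAR)
missingness, genotyping error, age/sex confounding unless configured,
myeloma-specific mortality (only all-cause follow-up), and real per-allele
weights — the bundled weight file is synthetic (realistic 48–120 bp
magnitudes, se ≈ β/6) and is labelled as such. Consequently, passing tests
demonstrate the *statistical machinery* (calibration, unbiasedness, coverage,
bookkeeping) under the stated design, not agreement with any particular
published coefficient; MR coefficients computed from the published outcome
tables reproduce the published standard-error scale but depend on the true
exposure weights for their values.

## Numerical choices and degenerate inputs

- HWE: 1-df Pearson χ² (classical, closed-form testable); monomorphic SNPs
  return χ²=0, p=1, flagged. Computed in controls by default. QC is
  reporting-only — nothing is auto-dropped.
- Logistic: perfect separation raises an error naming the suspect term(s);
  rank-deficient designs raise an error listing collinear columns. Inside the
  per-SNP scan these conditions (sparse codominant cells at small n) skip the
  affected model with a warning instead of aborting the scan.
- Cox: constant columns are rejected (inestimable in a partial likelihood);
  fewer than 2 events in a survival stratum is an error.
- Wald ratio requires `bx ≠ 0`; IVW requires some nonzero `bx`; Egger requires
  K ≥ 3 and non-constant `bx`.
- Quintile degeneracy (all reference values equal) warns and maps everything
  at the value to quintile 1.

## Problem sizes in the test suite

Calibration and recovery studies use 500 replicates of n = 20,000 cohorts
(coverage bands [0.92, 0.98], type-I error within 3 binomial SDs of 0.05),
a 2,000,000-subject single run for the marginal-slope oracle, 2,000 simulated
SNP columns (n = 500, MAF 0.3) for HWE uniformity, and 1,000 summary-level
replicates for MR coverage/pleiotropy power; the whole suite runs in a few
minutes on one CPU.

## Known limitations

- The published per-allele bp effects (and their SEs, needed for I²GX) are
  configuration inputs; without them the MR coefficients from published
  outcome tables are not comparable to the published values.
- No exact HWE test, no multiple imputation of covariates, no LD-aware
  scoring, no weighted-median/MR-PRESSO estimators, no competing risks.
- VCF input takes the first ALT only and rejects multi-allelic records at
  panel positions; no strand-flip inference is attempted beyond the explicit
  allele-label match.
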