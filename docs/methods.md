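# Methods

## The estimand and the two models

For each outcome we estimate the association of a standardized polygenic
score (PGS) with the outcome twice:

1. **Population model.** A GLM with logit link (binary outcomes, reported as
   OR per SD of PGS) or identity link (continuous outcomes standardized to
   SD units, reported as standardized β), adjusted for age, sex, genotyping
   chip, eight genotype PCs and chip×PC interactions. Families induce
   within-cluster correlation, so inference uses the cluster-robust sandwich
   covariance B⁻¹MB⁻¹: B is the Fisher information (X'WX), M the sum over
   families of outer products of within-family score sums, multiplied by
   G/(G−1) for G clusters. Point estimates come from the working-independence
   fit; this reproduces a GEE with independence working correlation. Wald 95%
   CIs use ±1.96·SE. Variance explained by the PGS is the Nagelkerke
   pseudo-R² difference between the full model and the covariates-only model
   (logit; the normalizer uses the intercept-only log-likelihood) or the
   plain R² difference (identity).

2. **Within-sibling model.** Full siblings (same non-missing father and
   mother, ≥2 members with complete data) form strata. Continuous outcomes:
   all variables demeaned within sibship, least squares on the demeaned data,
   sibship-clustered sandwich SEs whose small-sample correction counts the
   absorbed sibship means as parameters. Binary outcomes: conditional
   logistic regression, conditioning on the per-stratum case count, which
   eliminates the stratum intercepts; outcome-concordant sibships carry no
   information and are only counted. The conditional likelihood's subset-sum
   denominator and its gradient are computed with the standard recursion over
   stratum members (exhaustive enumeration is used only as a test oracle);
   optimization is BFGS on the analytic gradient with Newton polishing to a
   gradient norm below 1e-8, SEs from the numerically differentiated observed
   information. Covariates with no within-stratum variation are absorbed and
   dropped, with a log entry.

**Between-versus-within comparison.** The between-sibling reference is the
population model refit on the sibling subsample, so attenuation cannot be an
artifact of sample composition. The formal test is a Wald test of coefficient
equality in a joint model containing the sibship-mean and the deviation
components of the PGS (family-clustered sandwich); the naive
z = (β_B − β_W)/√(SE_B² + SE_W²) from the two separate fits is reported
alongside for reference. Attenuation is 100·(β_within − β_between)/β_between
on the log-OR/β scale, undefined when β_between = 0.

Why the joint-model Wald test: the two separate fits share data, so the naive
z ignores their covariance; regressing on (mean, deviation) orthogonalizes
the two components and gives the equality test a clean clustered covariance.
This is a design choice where several constructions are defensible; the
calibration test (p-values uniform under no familial confounding) is the
criterion it must satisfy, and both statistics are reported.

## PGS construction

QC removes strand-ambiguous variants (A/T, C/G allele pairs) and keeps
MAF > 0.01 and INFO > 0.8 — strict inequalities, matching the usual "MAF >
1%" phrasing. Harmonization intersects on variant id; a weight is kept when
the counted (ALT) allele equals the effect allele, negated when it equals the
other allele, and the variant is dropped on any other allele configuration.
Clumping is greedy: the remaining variant with the smallest p-value becomes
an index (ties broken by chromosome, position, id — making the result
independent of row order), and remaining variants within 250 kb on the same
chromosome with dosage r² > 0.1 against the index are removed. Clumping runs
before thresholding, as in standard PLINK practice. Scores at the 11
canonical thresholds (p ≤ t, inclusive) are z-scored; the final PGS is the
first principal component of those columns (correlation-scale PCA),
sign-aligned to correlate non-negatively with the column mean so that
"higher score = higher risk" is reproducible. Missing dosages are
mean-imputed per variant at scoring time (switchable; the choice only
matters for data with missingness).

## Phenotype harmonization

Fixed order, recorded in the preparation report:

1. Medication back-correction: LDL/0.7 and triglycerides/0.8 under
   lipid-lowering medication; +15/+10 mmHg on systolic/diastolic pressure
   under BP-lowering medication; glucose and HbA1c set missing under diabetic
   medication (no accepted back-correction exists). A provenance marker
   blocks accidental double application.
2. Outlier trimming: values beyond 4 SD of the mean set missing, with mean
   and SD computed once (single pass, the literal reading of the rule; an
   iterated rule would remove more).
3. Natural-log transform of the listed right-skewed biomarkers (leucocytes,
   HbA1c, glucose, HDL, triglycerides, ALT, AST, alkaline phosphatase,
   gamma-GT, creatinine, creatinine clearance, urine albumin, uric acid, TSH,
   free-T3, free-T4, ACR, UAE). hsCRP is deliberately not on this list.
4. z-scoring of all continuous measures over non-missing values. z-scores
   are recomputed within each analysis sample (e.g. the sibling subsample).

Derived variables: obesity = BMI ≥ 30 (boundary inclusive); education
categories map to years {1, 7, 10, 13, 20} with "high" attainment = the
20-year categories (higher vocational / university); any-metabolic and
any-cardiovascular disease are logical ORs of their components, treating a
missing component as 0 unless all components are missing. Stratified
analyses split age at 60 with 60 assigned to the older stratum, a logged
convention. Multiple testing uses Benjamini–Hochberg across all tests
emitted in one pipeline run (one pooled family per run; per-family FDR is
available).

## The synthetic cohort

The generator encodes the causal diagram the sibling design addresses.

- **Genotypes.** Per variant, a base allele frequency from
  `allele_freq_range` (default U(0.1, 0.5)). Haplotypes are drawn by
  thresholding a latent AR(1) Gaussian within blocks of `block_size`
  variants (default 10, lag-1 correlation 0.6), giving tunable LD for the
  clumping step with no recombination model; blocks are independent. Each
  offspring receives one uniformly chosen parental haplotype per block from
  each parent — expected child dosage equals the midparent dosage and
  full-sib PGS correlation is ½ under random mating.
- **True weights.** One causal variant per block (the block's first variant)
  with weight ~ N(0, 0.05²); all other variants are null. This placement
  makes "clumping retains the causal signal" achievable by construction, so
  score–truth correlation → 1 in the noiseless-weights limit.
- **Summary statistics.** Estimated weight = true weight + N(0, gwas_se²)
  (default SE 0.01), Wald p-values; at gwas_se = 0 the estimates are exact
  and null variants get p = 1. By default 5% of variants each get ambiguous
  alleles, a reported MAF below 1%, or INFO below 0.8, to exercise QC; runs
  that target analytic recovery values switch these off and use
  gwas_se = 1e-3.
- **Phenotypes.** Per-biomarker liability
  `sign·(β_d·S + β_n·S̄_parents) + F + ε` with family environment
  F ~ N(0, 0.15), subpopulation environment offset when configured, and
  residual ε sized by default so the liability has unit variance
  (`SimConfig.noise_for_unit_variance`). Defaults β_d = 0.2, β_n = 0.3 —
  small effects of the order seen for disorder PGSs, large enough for
  desk-scale power. HDL carries a negative effect sign. Liabilities map to
  lab scales via the panel's means/SDs (log-normal for the skewed markers,
  floored at 1% of the mean otherwise, since lab values cannot be negative).
  Diseases are liability-thresholded at the empirical (1 − prevalence)
  quantile with paper-like default prevalences; medication flags mark the
  upper decile of LDL, systolic BP and glucose; a self-reported ADHD-like
  flag thresholds S + noise at 1% prevalence. Age ~ N(44.4, 13.6²) clipped
  to [18, 90], 59% female, education categories with ~26% higher education,
  two chip labels (71.5/28.5%).
- **Population structure.** With two subpopulations, allele frequencies are
  offset ±`freq_divergence`/2; for causal variants the offset is aligned
  with the weight's sign so subpopulation 2 has the higher mean genetic
  liability — the confounded configuration the design must withstand —
  while null variants diverge in random directions. Genotype PCs are
  computed by plain PCA on mean-centered founder dosages and projected onto
  the offspring (with a canonical sign convention so sample order cannot
  flip a component). Assortative mating rank-matches a liability proxy
  (β_d·S + environment-scaled noise, standardized) using a noisy key, a
  deterministic construction whose spouse correlation approaches
  `mate_corr`.
- **Seeds.** One master seed; every stochastic operation draws from a named
  substream (CRC-32 of the operation name), so stages are independently
  reproducible and the whole study is bit-identical across runs.

**What the generator does not emulate** — realistic human LD maps and
recombination, imputation error structure, sex chromosomes, measurement
error in biomarkers beyond the additive residual, missing data, real
disease operationalization from medication/ICD codes, and participation
bias. Passing tests therefore show that the statistical machinery recovers
known parameters under an additive generative model, not that any real
cohort satisfies that model.

## Numerical choices

- Logit fits: IRLS (Newton) to score norm < 1e-8 or 100 iterations, with
  step damping; a coefficient beyond ±15 on the logit scale flags probable
  perfect separation and marks the result non-estimable.
- Collinear design columns are dropped by pivoted QR with an
  eps-times-dimension tolerance, with a warning.
- The clustered sandwich applies G/(G−1) only (the fixed-effects variant
  additionally applies (N−1)/(N−G−k) for the absorbed means); the reference
  implementation used for cross-checking applies an extra (N−1)/(N−k), an
  exactly known factor the tests account for.
- Zero-variant thresholds produce all-zero raw and z columns with a warning;
  constant columns are excluded from the PCA with the variance-explained
  fraction computed over the remaining ones.
- Ties in clumping p-values break by (chromosome, position, id); score
  membership is p ≤ threshold inclusive.
- Complete-case analysis per outcome; fits refuse samples below 50 complete
  cases.

## Problem sizes

Unit and property tests run at 80–5,000 families with 30–300 variants;
the calibration suite uses 500 replicates of 150 families and the coverage
suite 500 replicates of 100 clusters × 4 members; the recovery analyses use
5,000 families × 2 siblings with 300 variants (one causal per 5-variant
block). These sizes give Monte-Carlo error comfortably inside the stated
tolerances while keeping any single suite under a few minutes on one core.

## Known limitations

- The conditional-logistic SE comes from numerically differentiated observed
  information; for very large strata an analytic second-order recursion
  would be faster and slightly more precise.
- The attenuation percentage is a ratio statistic; its delta-method SE is
  reported nowhere and it is unstable when the between estimate is near 0.
- The joint-model comparison test assumes the same covariate effects in the
  between and within components.
- Binary-outcome effect sizes depend on the liability-threshold
  construction; log-ORs from thresholded liabilities are not numerically
  equal to the liability-scale βs (the recovery targets are stated on the
  continuous scale for this reason).
- Working-independence estimation is consistent but not fully efficient
  under strong within-family correlation; a full GEE working-correlation
  family is out of scope.
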