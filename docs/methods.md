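# Methods

This note documents the models, the synthetic-data generator, the
numerical conventions, and the design choices behind `prsdelta`. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Score model

A polygenic risk score is the weighted dosage sum `PRS_i = Σ_j β_j K_ij`
over the SNPs of one weight table, where `β_j` is the per-allele log odds
ratio published for the *effect allele* and `K_ij` counts copies of that
allele. The printed summation convention of such formulas is sometimes
off by one; here the sum runs over exactly the matched scoring SNPs, and
`n_snps_used` records how many survived harmonization.

**Harmonization.** Weight tables and genotypes are matched by rsID, not
position (GWAS portal tables key on rsID). If the effect allele is the
matrix's counted (ALT) allele the dosage is kept; if it is the other
allele the dosage becomes `2 − K`; any other configuration is excluded
with reason `allele_mismatch`. Strand-ambiguous SNPs (A/T, C/G) are
excluded by default because without frequency metadata a strand flip is
undetectable; `allow_ambiguous=True` disables this. Harmonization is
involution-safe: re-harmonizing an oriented matrix is a no-op.

**Missing genotypes** are mean-imputed per variant (the mean of observed
dosages equals twice the effect-allele frequency). This is standard score
practice: it keeps the analyzed *n* constant across scores and preserves
each variant's mean dosage. A fully missing variant is an error. No
per-individual call-rate filter is applied by default.

**Standardization** divides by the sample SD (ddof = 1) of the analyzed
cohort, computed after exclusions, so association coefficients are trait
units per SD of the score *in this cohort*. Zero-variance scores raise an
explicit error rather than returning NaNs.

## Statistical battery

* **Eligibility.** IFG ⇔ 100 ≤ fasting glucose ≤ 125 mg/dL; HbA1c range
  ⇔ 5.7 ≤ HbA1c ≤ 6.4 %; IGT ⇔ 140 ≤ 2 h glucose ≤ 199 mg/dL; all bounds
  inclusive; eligible ⇔ any flag. The criteria-overlap summary reports
  |IFG ∩ HbA1c| as a percentage of the cohort to one decimal.
* **Paired comparison.** Δ = T2 − T1 per trait; missing visits propagate.
  Wilcoxon signed-rank, two-sided; zero differences dropped; exact null
  for ≤ 25 tie-free differences, tie-corrected normal approximation
  otherwise; all-zero difference vectors are flagged degenerate with
  p = 1. Medians and IQRs use linear-interpolation quantiles, reported as
  (Q1, Q3). Shapiro–Wilk on Δ is logged per trait as a diagnostic only —
  the nonparametric path is always taken, since metabolic panels of this
  kind are reliably non-normal.
* **Association.** OLS with Wald t intervals (df = n − k − 1) and
  adjusted R² = 1 − (1 − R²)(n − 1)/(n − k − 1). Baseline models adjust
  for age and sex; change models for age, sex, and *baseline* BMI (not
  Δ BMI), which is why the change-trait family has 16 members (BMI is the
  covariate). Sex is coded 1 = female / 0 = male; the per-SD score
  coefficient is invariant to this choice. Robust (heteroskedasticity-
  consistent) errors and bootstrap intervals are deliberately out of
  scope: Wald intervals match the conventional "β (95 % CI)" reporting.
* **Multiple testing.** Benjamini–Hochberg step-up within each analysis
  family: the 17 baseline traits; the 16 change traits per score; each
  sex stratum separately; and the full SNP × trait grid in the genotype
  stratification. Family boundaries follow how such tables are printed —
  one family per reported table.
* **Sex stratification** re-fits the change models within each sex with
  the sex covariate dropped (it is constant); strata under 10 individuals
  are skipped with a warning.
* **Genotype stratification.** Individuals partitioned by hard-call
  effect-allele dosage (0/1/2); fractional (imputed) dosages are treated
  as missing here, so stratification should run on pre-imputation calls.
  Kruskal–Wallis with midranks and tie correction against χ²(k−1);
  pairwise Wilcoxon rank-sum post hoc (exact when both groups ≤ 10 and
  tie-free, else tie-corrected normal without continuity correction).
  Post-hoc p-values are reported unadjusted by default (a flag adds BH
  across comparisons). Records are emitted for pairs with FDR-adjusted
  p < 0.05 or raw p < 0.1 — the latter a "tendency" band mirroring how
  borderline genotype effects are conventionally reported.
* **HWE.** χ² goodness of fit with 1 df against (p̂²N, 2p̂q̂N, q̂²N);
  monomorphic SNPs are flagged untestable rather than erroring. An exact
  test (Levene's conditional distribution of the heterozygote count given
  the allele count, two-sided by probability ordering) is available for
  small counts.

## Synthetic-cohort generator

The generator is the package's substitute for non-public cohort data; its
defaults define the study conditions used throughout the tests.

* **Panel.** 68 T2D-score SNPs and 21 obesity-score SNPs sharing 20
  (69 unique). MAFs uniform on [0.05, 0.5]; |β| uniform on [0.01, 0.15],
  positive for the effect allele — published per-allele log odds ratios
  for common metabolic variants rarely exceed ~0.15 and the source
  portals do not fix a distribution, so this is an explicit artifact
  choice exposed in the config. REF/ALT pairs are drawn from the four
  non-strand-ambiguous combinations; the effect allele is ALT for ~80 %
  of SNPs and REF for the rest so harmonization is exercised on realistic
  input.
* **Genotypes.** ALT dosage ~ Binomial(2, MAF) per SNP: Hardy–Weinberg
  proportions, no linkage disequilibrium, no population structure (both
  deliberate non-goals).
* **Covariates.** Sex ~ Bernoulli(0.549) (the female share of the
  emulated cohort); age uniform over [30.33, 55.73] years (its
  interquartile span). These give plausible covariate structure without
  claiming the real joint distribution.
* **Baseline traits.** Uniform over per-trait ranges set to cohort-scale
  interquartile spans; fasting glucose and HbA1c are constrained to the
  prediabetic diagnostic ranges for a configurable fraction of
  individuals (default 0.9) and sampled just *below* threshold for the
  rest, so eligibility classification sees both sides of every bound.
* **Follow-up.** `T2 = T1 + shift + γ·zPRS + covariate terms + ε`,
  ε ~ N(0, σ). Effects are linear on the *change* scale, matching the
  analysis target; a per-trait constant `shift` models secular drift. An
  optional per-trait baseline effect on zPRS exists for baseline-
  association experiments. The driving score (T2D or obesity) is
  configurable.
* **Residual SD.** Default σ = 0.05 trait units for every trait. This is
  chosen so per-SD effects of the magnitude reported in this literature
  for cohorts of a few hundred (order 0.005 trait units per SD) are
  estimable: at n ≈ 450 the coefficient SE is ≈ σ/√n ≈ 0.0024, putting a
  0.005 effect ~2 SE from zero. Real metabolic traits have far larger —
  and heterogeneous — residual variability; passing calibration tests
  therefore demonstrates correctness of the machinery at these scales,
  not field realism of any single trait's variance.
* **Reproducibility.** One integer seed; named sub-streams
  (panel/genotypes/phenotypes/missingness) derived via `SeedSequence`
  spawning, so `simulate_weight_tables(cfg)` returns byte-identical
  tables to those inside `simulate_cohort(cfg)` and the full pipeline is
  byte-reproducible.

What the generator does **not** model: linkage disequilibrium, population
stratification, ancestry-specific effect sizes, genotyping batch effects,
non-Gaussian residuals, trait–trait correlation, and informative
missingness. Calibration results on synthetic cohorts say nothing about
those failure modes in real data.

## Calibration experiments (`prsdelta.validation`)

Replicate experiments run the full simulate → harmonize → score → delta →
associate path per replicate, with per-replicate seeds derived from one
master seed:

* type-I error: 1000 null cohorts of n = 200, per-trait raw rejection
  rate at α = 0.05 and mean FDR discoveries per 16-trait family;
* effect recovery: 1000 cohorts of n = 400 with γ = 0.005 on Δ fat mass;
  95 % CI coverage of γ and sign agreement of the estimate;
* generator self-consistency: HWE pass rate at α = 0.001 over 30 cohorts
  of n = 446 (2070 SNP draws), and mean raw score at n = 10,000 against
  its expectation Σ_j 2 p_j β_j in Monte-Carlo SEs.

The replicate counts are chosen to keep Monte-Carlo standard errors small
relative to the tolerances being checked (e.g. SE ≈ 0.7 % for coverage at
1000 replicates) while completing in a few minutes on one CPU.

## Numerical conventions and edge cases

* Quantiles: NumPy linear interpolation throughout.
* Ties: midranks everywhere; signed-rank drops zeros; exact enumerations
  are only used on tie-free data.
* Degenerate inputs raise typed errors naming the offending field,
  variant, or column (`ConfigError`, `MissingVariantError`,
  `DegenerateScoreError`, `CollinearityError`), except where a flagged
  result is more useful (monomorphic HWE, all-zero paired differences,
  identical pooled Kruskal–Wallis values).
* VCF: 4.2, GT field only, one ALT per record; multi-allelic and
  non-SNP records are skipped and counted. Coordinates are 1-based.

## Known limitations

* No clumping/thresholding or shrinkage score optimization — the weight
  tables are taken as given.
* No reference-panel imputation, phased data, indels, or DS-field
  dosages.
* The command-line `run` bundle persists intermediates as TSV; very large
  cohorts would want a binary genotype format, which is out of scope.
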