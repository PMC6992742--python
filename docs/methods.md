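# Methods

## Model and procedure

The pipeline estimates how much older or younger a brain looks than those
of age-matched peers, and tests that quantity against exposures and
genotypes.

1. **Split.** Subjects are randomly partitioned into a training set of
   ⌈0.30·n⌉ and an evaluation set of the remainder (this ceiling rounding
   is the only rule consistent with a 5,193 / 12,115 split of 17,308).
   All model fitting uses the training set only; all association testing
   uses the evaluation set only, so the statistic is never tested on the
   data that built it.
2. **Brain-age model.** Lasso linear regression of chronological age (CA)
   on all morphometric features — no pre-selection. Features are
   standardized to zero mean / unit variance before penalization; the
   penalty λ is chosen by 10-fold cross-validation over a geometric grid
   of 100 values. The prediction is PBA.
3. **Two-stage correction.** OLS of PBA on CA in the training set gives
   EPBA(ca) = α + β·ca; RBA = PBA − EPBA(CA). On the training set
   mean(RBA) = 0 and corr(RBA, CA) = 0 exactly (OLS residual
   orthogonality); on the evaluation set both hold up to sampling error.
   The same training-fit line is applied unchanged to evaluation
   subjects; re-fitting EPBA on evaluation data is possible via
   `fit_epba` but is not the default, because the statistic should be a
   fixed function of anatomy and age learned on training data.
4. **Associations.** Category effects are tested by extra-sum-of-squares
   F (covariates always retained); continuous exposure effects by a
   two-step OLS in the configured subset (by convention daily smokers who
   drink): fit, exclude observations with Cook's distance > 3× mean
   Cook's distance, refit exactly once, report the refit. Per-SNP tests
   are 1-df additive t-tests and 2-df additive+heterozygote F-tests
   against a covariate-only null, complete cases per SNP, flagged at
   p < 5×10⁻⁸.

### Why the correction matters

With noisy predictors the best linear prediction of age is attenuated:
PBA ≈ c + m·(CA + δ) with m < 1, where δ is the subject's latent aging
offset. Hence PBA − CA = (m−1)·CA + m·δ + ε is negatively correlated with
CA even under the null — an artefact, not biology. Subtracting the fitted
PBA-on-CA line removes the (m−1)·CA term, leaving RBA ≈ m·δ + ε. Note the
attenuation factor m also multiplies δ: effect sizes estimated on RBA are
biased toward zero by the same factor. Under the default generator
conditions m ≈ 0.93, so recovered exposure slopes sit ~5–8% below the
injected values — visible in the acceptance replicates and inherent to
any brain-age-based effect estimate, not a defect of the implementation.

## Synthetic cohort generator

The generator emulates the statistical skeleton of a large population
imaging cohort; defaults are the study conditions every test runs under.

| parameter | default | meaning |
|---|---|---|
| age range | 45.2–80.7 y | CA ~ Uniform |
| n_features / informative | 403 / min(50, n_features) | morphometric panel |
| feature slopes | ±Uniform(0.6, 1.4) units/y | sign random per feature |
| feature noise sd | 8 units | per feature |
| beta_smoke | 0.03 y per pack-year | injected into `true_delta` |
| beta_alcohol | 0.02 y per g/day | injected into `true_delta` |
| delta_sd | 2.5 y | residual spread of `true_delta` |
| smoke_alcohol_corr | 0.08 | Pearson, daily smokers who drink |
| maf_range | (0.05, 0.5) | per-SNP ancestral MAF |
| apoe_e4_freq / beta_apoe | 0.15 / 0 | independent {0,1,2} column |

Informative features respond to *effective age* CA + `true_delta`, so
exposure and SNP effects reach the age model only through anatomy — the
causal pathway the analysis presumes. Smoking frequency determines the
pack-year distribution (never/tried: 0; occasional: log-normal around 2;
daily: log-normal with mean 20 y, sd 15 y), and alcohol frequency scales
grams/day (log-normal medians 2–24 g across categories, σ = 0.6). The
0.08 exposure correlation is induced through a Gaussian copula whose
latent correlation is the exact bivariate-log-normal inversion of the
target Pearson value. Fluid intelligence is an integer 0–13:
round(clip(6.5 − 0.06·centered δ + N(0, 2.1))), a deliberately weak
negative link. Genotypes are binomial HWE draws; two subpopulations use
Balding–Nichols frequencies at the configured divergence; full-sib pairs
share two simulated parents; missingness is masked uniformly.

The variance budget behind the defaults: Var(CA) ≈ 105 y², Var(δ) ≈ 6.6
y², and the feature panel leaves a residual of ~1.3 y² when recovering
effective age, giving m ≈ 0.93 — strong enough dilution to demonstrate
the artefact (corr(PBA−CA, CA) ≈ −0.3), mild enough that injected effects
are recoverable within 10%.

What the generator does **not** emulate: correlated morphometric features
(real regional volumes co-vary strongly), linkage disequilibrium between
SNPs, haplotypes or sex chromosomes, non-linear age trajectories,
selection effects in cohort recruitment, and any direct exposure→feature
pathway bypassing the latent offset. Passing tests therefore show the
machinery is correct and calibrated under the assumed structure, not that
the scientific conclusions transfer to any particular real cohort.

## Genotype QC details

* **HWE exact test:** conditional on allele counts, sums probabilities of
  all heterozygote counts no more probable than observed (two-sided
  exact, no mid-p), computed by the standard two-term recurrence scaled
  to the mode. Agrees with exact rational enumeration to ~1e-15 for all
  tables up to 200 subjects.
* **Filters:** SNP missing rate < 0.02 and HWE p ≥ 1e-6; sample call
  rate > 0.98 and heterozygosity within ±3 SD of the mean of
  call-rate-passing samples (SD = 0 removes nobody). Filters are
  idempotent.
* **Kinship:** KING-robust within-family estimator
  φ = (N_AaAa − 2·N_AA,aa)/(N_Aa⁽ⁱ⁾ + N_Aa⁽ʲ⁾) over SNPs non-missing in
  both samples — robust to allele-frequency structure; ≈0.5 for
  duplicates, ≈0.25 for full sibs. Pairs above 0.1 are pruned greedily,
  highest kinship first, dropping the member with more missingness (ties:
  the lexicographically larger id) — a deterministic rule. Kinship noise
  scales as ~1/√(#SNPs); below ~2,000 SNPs spurious pairs above 0.1
  appear, so simulations that exercise pruning use ≥2,000 SNPs.
* **PCA:** SVD of the column-standardized dosage matrix (missing imputed
  to SNP means, monomorphic SNPs dropped), components ordered by variance
  with each component's largest-magnitude loading made positive (a
  deterministic sign convention). No LD pruning — synthetic SNPs are
  unlinked; a pruning pre-step can be inserted before the call.

## Numerical and design choices

* λ at the CV minimum by default. The one-standard-error rule is exposed
  (`lambda_rule="1se"`) and is the right choice when the goal is support
  recovery: at n = 5,000 with 5 informative of 403 features, CV-min
  selects ~17 features (the 5 real ones plus noise), while 1-SE selects
  exactly the 5. CV-min is kept as the default because its weaker
  shrinkage minimizes the attenuation of downstream effect estimates.
* Whether to standardize features before the lasso is a free choice; we
  standardize (the penalty then treats features symmetrically) and store
  means/scales in the serialized model.
* Cook's-distance exclusion is single-pass by design: one exclusion, one
  refit, never iterated.
* Pairwise contrasts report raw and Bonferroni-adjusted p side by side;
  the choice of correction is left to the user.
* The "genotypic" SNP test is the 2-df joint test of dosage plus a
  heterozygote indicator — additive and dominance deviations — against
  the covariate-only model; the additive 1-df test is always reported
  because effect direction is of interest.
* Degenerate inputs fail loudly: constant response, non-finite features
  (named), categories with <2 subjects (named), monomorphic dosage
  columns, rank-deficient designs, k above matrix rank.
* Missing phenotype values are handled complete-case per analysis, with
  `n_used`/`n_missing`/`n_excluded_influential` accounted so that they
  always sum to the input size.

## Problem sizes in tests and acceptance

Single-run checks (dilution correlations, MAE band) use n = 5,000 with
the full 403-feature panel. Replicate-heavy checks (100-replicate effect
recovery at n = 10,000, power and calibration) use a reduced 60-feature
panel with the same noise-per-feature and 40 informative features, which
preserves the variance budget (m ≈ 0.93) while keeping each lasso fit
fast; calibration uses 5,000 null replicates for the ANOVA/interaction
tests and 10,000 null SNPs for the per-SNP test, so that the Monte-Carlo
error of a 5% rejection rate (±0.006 / ±0.004) is small against the
[0.04, 0.06] acceptance band. Power uses 25 replicates of a 0.6 y/allele
causal SNP at MAF 0.25–0.35, n = 5,000 — conditions set from the power
calculation (expected non-centrality ≈ 8.9, i.e. comfortably above the
genome-wide threshold), not tuned afterwards.

## Known limitations

* Effect estimates on RBA inherit the attenuation factor m of the
  brain-age model; the package reports what the two-step regression
  estimates, which is the attenuated effect (as any such analysis does).
* The EPBA line is estimated, so evaluation-set corr(RBA, CA) is zero
  only in expectation; at n = 5,000 its sampling spread is ~0.03.
* The kinship estimator needs a few thousand SNPs for stable pruning.
* The generator's exposure-category joint distribution is configurable
  but by default independent of age and sex, which real questionnaires
  are not.
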