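# Methods

`liabsem` decomposes the common-variant liability of three correlated
psychiatric disorders — schizophrenia (SCZ), bipolar disorder (BD) and
major depressive disorder (MDD) in the default configuration — into one
**shared** component and three **disorder-differentiating** components,
then asks whether polygenic scores for those components track symptom
dimensions within a bipolar-disorder cohort.  This note records the models,
the estimation choices, the synthetic-data design and its limits.

## 1. Genetic covariance estimation (LD score regression)

For each study the per-variant association statistic is regressed on LD
scores `l_j = sum_k r2_adj(j,k)` computed from a reference genotype panel
within a 1 Mb window, with the small-sample correction
`r2_adj = r2 - (1 - r2)/(n_ref - 2)` and the self term fixed at 1:

* univariate: `E[chi2_j] = 1 + N h2 l_j / M`; the slope is the SNV
  heritability on the observed (0/1 regression) scale, the free intercept
  absorbs confounding;
* bivariate: `E[z1_j z2_j] = rho_ns + sqrt(N1 N2) rho_g l_j / M`; the free
  intercept absorbs the correlation of estimation errors caused by shared
  participants (here: shared controls), so overlap does not bias the
  covariance slope.

Weights are the standard heteroskedasticity form
`1/(max(l,1) (1 + N h~2 l/M)^2)` (product of the two per-study factors in
the bivariate case) with the provisional `h~2` from an unweighted first
pass; one reweighting pass only.  Variants with `chi2 > max(80, 0.001 N)`
are excluded from the regressions.  Sampling covariances of all K(K+1)/2
unique elements of S come from a delete-one-block jackknife over 200
contiguous equal-count variant blocks; the resulting V is projected to the
nearest positive semidefinite matrix when jackknife noise makes it
indefinite (the clipped eigenvalue magnitude is recorded).  Jackknife SEs
are well calibrated from roughly 2,000 variants upward; below that the
200-block partition leaves too few variants per block and the SE is mildly
anticonservative, which is why the calibration tests run at 2,000+.

Heritabilities are reported on the observed scale throughout the main
path.  `observed_to_liability_h2` / `liability_to_observed_h2` implement
the standard ascertainment-aware threshold-model conversion and are used
only for cross-checking the simulator.

## 2. Common-factor model and per-SNV decomposition

The baseline structural model on the K x K genetic covariance matrix is a
single latent factor F with unit variance:
`sigma_kl = lambda_k lambda_l`, `sigma_kk = lambda_k^2 + psi_k`.
Estimation is diagonally weighted least squares (DWLS): minimize
`(s - sigma(theta))' D^-1 (s - sigma(theta))` with `D = diag(V)`.
Standard errors use the sandwich
`(J'D^-1 J)^-1 J'D^-1 V D^-1 J (J'D^-1 J)^-1`.  With K = 3 the model is
just-identified (df = 0): the fit reproduces S exactly and the loadings
have the closed form `lambda_1 = sqrt(s12 s13 / s23)` (and rotations),
which doubles as the optimizer's start and as an exactness test.

Per variant, S is bordered with the SNV as a unit-variance variable whose
trait covariances are the standardized effects `beta_k = z_k / sqrt(n_k)`.
Sampling variances of these moments are `1/n_k`; their cross-study error
covariances are `intercept_kl / sqrt(n_k n_l)` from the LDSC cross-trait
intercepts — this is where sample overlap is corrected.  Two models are
fitted per variant, both with all loadings free:

* **shared effect**: F regressed on the SNV (`F = b SNV + d`); `b` is the
  variant's effect carried through the factor;
* **differentiating effect for disorder t**: the same model plus a
  simultaneous direct path SNV -> trait t; the direct coefficient is the
  effect on disorder t beyond the factor.  The two eFigure-style
  orthogonalizations (simultaneous path versus residualized) coincide for
  the null and proportional cases; the simultaneous-path version is used
  because it keeps the factor regression honest when a variant has both
  kinds of effect.

Residual variances are parameterized as `psi = q^2`, which enforces
`psi >= 0`, removes the improper escape ray `lambda -> inf, psi -> -inf`,
and turns the Heywood boundary `psi = 0` into a stationary point; boundary
solutions are reported as psi = 0 and flagged.  Genome-wide application
runs a vectorized Levenberg–Marquardt over all variants simultaneously
(analytic Jacobians, per-variant damping).  Convergence is a weighted
gradient below 1e-7; because the q parameterization approaches the
boundary quartically slowly, a stalled objective with gradient below 5e-3
after snapping `|q| < 1e-2` to zero is also accepted — at the weights used
this bounds the error on the reported effect by ~1e-5, far below its
standard error.  Stragglers are refitted per-variant with
`scipy.optimize.least_squares`; a run aborts if more than 1% of fits fail.
P values are two-sided normal Wald tests on the sandwich SE; no genomic
control is applied to the derived sets.

Derived summary statistics carry `n_eff` = per-variant median of the
source-study n, recorded as metadata only.

## 3. Polygenic scoring

Clumping is the classical greedy procedure: visit variants by ascending p
(ties broken by chromosome, position, then id — determinism is asserted,
PLINK's internal tie order is not relied on); each index retires unretired
variants within ±500 kb with `r2 > 0.2` on the target sample's genotypes
(mean-imputed for correlation only).  Variants with target MAF < 0.1 or
imputation info < 0.7 are never indices and never scored.  Scores are the
unthresholded weighted allele counts over retained variants — p-value
thresholds cannot be tuned for factor-derived statistics without an
independent tuning sample — standardized to mean 0, SD 1 (ddof = 1).
Individuals missing more than 5% of retained genotypes get a missing,
flagged score; smaller gaps are mean-imputed.

## 4. Association suite

Phenotypes: psychosis = ordinal psychosis scale (BADDS-P) >= 10; MIPS =
incongruence scale (BADDS-I) >= 20, defined only where psychosis is
present because the scale is only rated then.  Records with a rated
BADDS-I but no psychosis violate the rating rule and are excluded from
MIPS models (flagged, never silently recoded).

Models: logistic regression for psychosis and MIPS; proportional-odds
cumulative-logit regression for the mania and depression scales and for
the ordinal sensitivity analyses of BADDS-P/I.  Covariates: age (linear),
genotyping platform (indicators), 10 principal components.  Conditional
analyses: psychosis adjusted for mania entered as category indicators
(avoiding a linearity assumption on an ordinal conditioner), and mania
adjusted for binary psychosis.  A sensitivity pass repeats everything with
schizoaffective-bipolar participants excluded.  PRS are re-standardized
within every analysis subset.  The ordinal optimizer is BFGS pushed to its
numerical floor with convergence judged on the score vector (infinity norm
< 1e-4) rather than the optimizer's own flag; with two outcome categories
the fit agrees with plain logistic regression to ~1e-9.  Betas are
reported as log odds (per SD of PRS); the two model families are not on a
common scale.  No multiple-testing correction is applied; all p are
two-sided.

Polychoric correlations use the two-step estimator (thresholds from the
inverse normal of marginal cumulative proportions, then rho by bounded
likelihood maximization over the contingency table, bivariate normal
rectangle probabilities via Owen's T).  The p value is a permutation
bootstrap under independence with an add-one correction; the default of
10,000 iterations is a desk-scale choice, configurable upward.

## 5. Synthetic study generator

The generator emulates the full study design with known truth.

**Genotypes.** Blockwise latent-Gaussian haplotypes: blocks of 20
variants, latent correlation `rho^|i-j|` with rho drawn per block from
U(0.5, 0.95), thresholded at the MAF quantile (MAF ~ U(0.05, 0.5));
genotypes are sums of two haplotypes.  This yields Hardy–Weinberg margins,
realistic within-block r2 spread (adjacent genotype r2 roughly 0.1–0.5) and
exact between-block independence.  Variants sit 1 kb apart across 22
chromosomes — a deliberately compressed map so that a 1 Mb LD window
always covers a block.

**Architecture.** Liabilities `L_k = lambda_k G_shared + G_k + eps`,
scaled to unit variance, with defaults lambda = (0.37, 0.36, 0.25) and
specific variances (0.10, 0.07, 0.09): SNV heritabilities ~0.24/0.20/0.15
and pairwise genetic correlations ~0.6/0.5/0.5, in the neighbourhood
reported for SCZ/BD/MDD.  20% of variants are causal per component,
independently drawn.  Prevalence is 15% for every disorder — far above the
clinical prevalences of SCZ and BD; this is the single largest concession
to desk scale, since case-control sampling at 1% prevalence would require
populations two orders of magnitude larger.  Consequences (milder
ascertainment distortion, smaller liability-to-observed scale factor) are
shared by all components, so comparative conclusions survive.

**Ascertainment.** One population (~75,000 at default settings) supplies
all samples.  The target cohort — 5,000 BD cases — is reserved first and
excluded from every GWAS, mirroring the custom source GWAS that left out
the PRS target sample.  Each study takes 5,000 cases and 5,000 controls;
half the controls come from a pool shared identically across studies
(screened for all disorders, as shared controls must be), the other half
are study-specific and screened only for the study's own disorder.  The
sharing produces cross-trait LDSC intercepts of about
`N_s / sqrt(n1 n2) ~ 0.25` that the SEM machinery must absorb.  GWAS z
statistics are the binary score test on genotype (equal to the
Cochran–Armitage trend z and to the linear-regression z).

**Symptoms.** Four latent symptom liabilities are linear combinations
`W G*` of the population-standardized genetic components plus Gaussian
noise topping variance up to ~1.  The default W follows the headline
cross-disorder pattern: psychosis (+shared, +SCZ-, +BD-, −MDD-specific);
incongruent psychosis (+SCZ-specific only); mania (+shared, +BD-,
−MDD-specific); depression (+MDD-, −BD-specific), with weights 0.15–0.30.
Ordinal BADDS-like scores come from fixed cutpoints chosen to give ~55%
psychosis among BD cases and 4–6 levels per scale; BADDS-I is generated
only where BADDS-P meets the psychosis criterion.  Age (mean 46.2, SD
12.3), two genotyping platforms (0.6/0.4) and 10 standard-normal PCs are
independent covariates.

**What the generator does not emulate:** real human LD maps and allele
frequency spectra, population stratification (the PCs are pure noise, so
covariate adjustment is exercised but never load-bearing), ascertainment
at clinical prevalence, rare variants, genotyping error and missingness
patterns, and any environment–symptom structure.  Passing tests therefore
demonstrate the estimators' internal correctness and calibration under a
faithful factor-structured design — not performance on real cohort data.

## 6. Problem sizes used in the tests

The end-to-end checks run at the generator's default conditions: 20,000
variants, three studies of 5,000 + 5,000, target cohort 5,000, one
2,000-sample reference panel.  LDSC recovery is assessed over 100
effect/noise replicates on one fixed 20,000 x 20,000 genotype matrix; the
null-calibration run uses 5,000 variants with zero disorder-specific
variance.  Uniformity of differentiating-effect p values is tested on the
per-block index variants (one per LD block), because the Kolmogorov–
Smirnov null assumes independent draws and within-block p values are
strongly dependent by construction; the all-variant tail rate is checked
separately.  The bootstrap default for polychoric p values is 10,000
rather than the 100,000 a production analysis would use.

## 7. Known limitations

* Per-variant sampling variance of `beta_k` is taken as `1/n_k`, ignoring
  the small polygenic inflation term; at the simulated heritabilities this
  understates the variance by <5% and the null-calibration tests bound the
  practical effect.
* The cross-study error covariance uses the raw cross-intercept estimate;
  a noisy intercept propagates into per-variant SEs.
* Heywood handling is clamp-and-flag; no formal boundary-corrected
  inference is attempted.
* The liability/observed scale conversions assume a strict threshold
  model with Gaussian liability — true in the simulator, approximate in
  reality.
* With fewer than ~2,000 variants the jackknife SE and hence V are
  unreliable; the pipeline runs but downstream SEs inherit the noise.
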