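# liabsem

Shared and disorder-differentiating genetic liability from GWAS summary
statistics, with downstream polygenic-score analysis of symptom dimensions.

Psychiatric disorders such as schizophrenia (SCZ), bipolar disorder (BD)
and major depressive disorder (MDD) are highly pleiotropic: their
common-variant liabilities correlate strongly (genetic correlations of
roughly 0.4–0.7).  Two individuals with the same BD diagnosis may carry
very different mixtures of alleles — some shared across disorders, some
relatively specific to one of them — and the hypothesis this package
operationalizes is that this mixture shapes the clinical picture: how much
psychosis, mania, depression, and mood-incongruent psychotic symptoms
(MIPS) an individual with BD experiences.

`liabsem` is a library for statistical geneticists who want to run or
stress-test this decomposition end to end:

1. **munge** — harmonize several GWAS summary-statistics tables to one
   reference orientation, with MAF/info/MHC quality control
   (`liabsem.sumstats`);
2. **LDSC** — estimate the genetic covariance matrix *S* (SNV
   heritabilities and covariances), its block-jackknife sampling
   covariance *V*, and sample-overlap intercepts by LD score regression
   (`liabsem.ldsc`);
3. **SEM** — fit a common-factor model to (*S*, *V*) by diagonally
   weighted least squares and, per variant, estimate the **shared effect**
   (SNV → factor) and three **differentiating effects** (SNV → disorder
   residual), yielding four derived genome-wide summary-statistic sets
   (`liabsem.gsem`);
4. **PRS** — greedily clump each derived set against target-sample LD
   (r² > 0.2 within ±500 kb, MAF ≥ 0.1, info ≥ 0.7) and compute
   standardized, p-value-unthresholded polygenic scores (`liabsem.prs`);
5. **associate** — derive symptom phenotypes from BADDS-style ordinal
   scales (psychosis = P ≥ 10; MIPS = I ≥ 20, rated only when psychotic)
   and run the full logistic / proportional-odds association grid with
   conditional and sensitivity analyses, plus polychoric phenotype
   correlations (`liabsem.assoc`);
6. **simulate** — generate every input with known ground truth: blockwise
   LD, liability-threshold case-control GWAS with a common factor and
   partially shared controls, and a BD-case target cohort whose symptom
   scales are configured linear combinations of the liability components
   (`liabsem.simulate`).

The model at the core: with genetic covariances
σ<sub>kl</sub> = λ<sub>k</sub>λ<sub>l</sub> (k ≠ l) and
σ<sub>kk</sub> = λ<sub>k</sub>² + ψ<sub>k</sub>, parameters minimize
(s − σ(θ))ᵀ D⁻¹ (s − σ(θ)) with D = diag(V); each variant then enters as a
unit-variance variable with trait covariances z<sub>k</sub>/√n<sub>k</sub>,
and its shared and differentiating path coefficients are estimated with
sandwich standard errors, the LDSC cross-trait intercepts supplying the
correlation of estimation errors due to sample overlap.

## Worked example

`examples/` contains one short script per capability.  The first fits the
factor model to a covariance matrix whose off-diagonals are exact loading
products:

```bash
$ python examples/01_common_factor_model.py
loadings:           [0.8 0.4 0.3]
residual variances: [0.36 0.84 0.91]
model chi2 (df=0): 3.08e-29
```

0.8 × 0.4 = 0.32, 0.8 × 0.3 = 0.24, 0.4 × 0.3 = 0.12 reproduce the three
covariances exactly; with three traits the model is just-identified, so
the fit statistic is numerically zero and the residual variances are the
diagonal remainders 1 − λ².

`examples/02_simulate_and_ldsc.py` simulates three overlapping
case-control GWAS and prints the estimated *S* alongside the intercept
matrix (positive off-diagonal intercepts from the shared controls);
`03_genomewide_decomposition.py` runs the per-SNV decomposition;
`04_clump_and_score.py` builds the four PRS and their correlation matrix;
`05_symptom_associations.py` runs the full association grid on a
simulated BD cohort and prints the conditional analyses and the
psychosis–mania polychoric correlation.

A thin CLI mirrors the steps for file-based use:

```bash
liabsem simulate --seed 1 --out sim/
liabsem munge --sumstats sim/sumstats_scz.tsv --sumstats sim/sumstats_bd.tsv \
    --sumstats sim/sumstats_mdd.tsv --names scz,bd,mdd \
    --ref sim/reference_variants.tsv --out panel.tsv
liabsem ldsc --panel panel.tsv --geno sim/reference.vcf --out cov.json
liabsem gsem --panel panel.tsv --cov cov.json --out-prefix derived/
liabsem prs --effects derived/shared.tsv --geno sim/target.vcf --out scores.tsv
liabsem assoc --scores scores.tsv --pheno sim/cohort.tsv --out results.tsv
```

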