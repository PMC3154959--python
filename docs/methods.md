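# Methods

`dimorph` implements a complete analysis chain for studying sexual
dimorphism in targeted serum metabolomics panels and its genetic
determination, together with a synthetic-data generator that reproduces the
statistical structure such studies assume. This note documents the models,
the defaults and why they were chosen, and what the synthetic data does and
does not emulate.

## Statistical models

### Per-metabolite sex effect

For each metabolite the natural-log concentration is modelled by ordinary
least squares,

    log c = b0 + beta_sex * male + covariates + batch indicators + e,

with male coded 1 and female 0, so a positive `beta_sex` means higher
concentrations in men. The base covariate set is age (years) and BMI
(kg/m^2); alternative sets substitute or add waist-hip ratio, lipid panel
(HDL, LDL, triglycerides), type-2-diabetes status, or smoking and alcohol
indicators. Inference for `beta_sex` uses the t-distribution with residual
degrees of freedom (at cohort sizes in the thousands this is
indistinguishable from the normal). The reported r^2 is the full-model
coefficient of determination, not the sex term's partial contribution —
the two can be computed from the same fit, and the full-model value is the
default because it is the conventional single-number model summary.

The relative sex difference is reported as

    Delta = 100 * (mean_men - mean_women) / mean_men   [percent],

computed on raw (unlogged) concentrations; it is negative when women have
the higher mean.

Multiple testing uses plain Bonferroni correction (alpha / number of
phenotypes). A discovery signal replicates when the replication-cohort
estimate has the same sign and a p-value below alpha divided by the number
of metabolites carried forward. Estimates from several cohorts are pooled
by inverse-variance fixed-effect meta-analysis (weights 1/SE^2, combined
SE = 1/sqrt(sum of weights)); the combined p comes from the pooled z.

The global male/female separation is visualized with two-component PLS1
scores (NIPALS, via scikit-learn) on the standardized metabolite matrix.
Component signs are fixed by requiring the first nonzero entry of each
weight vector to be non-negative, so scores are exactly reproducible.

### Partial-correlation network (Gaussian graphical model)

Full-order partial correlations between all metabolite pairs are obtained
by first residualizing each logged column against age, sex and BMI (with
intercept), then inverting the residual correlation matrix C:

    r_ij = -P_ij / sqrt(P_ii * P_jj),   P = C^{-1}.

Residualizing first is equivalent to carrying the covariates inside the
precision matrix and gives a directly testable contract: on small panels
the matrix-inversion result is checked against the brute-force oracle
(correlate the residuals of metabolites i and j after regressing each on
all other metabolites plus covariates) to 1e-8.

Edges are retained when |r| >= cutoff (default 0.3). The absolute-value
rule is used because strong negative partial correlations are as "direct"
as positive ones; in practice retained metabolite-metabolite edges are
almost all positive. Connected components of size >= 2 ("non-singleton
groups") are reported as independently regulated sub-phenotypes; singleton
nodes are kept in the graph but not counted as groups. No shrinkage is
applied by default — the intended regime is n >> p, and a singular
correlation matrix raises an error; a `ridge` argument exists as an
explicit small-n fallback. Exports are GraphML (default) or GML with node
attributes (compound class, beta_sex, p, significance marker) and the edge
attribute r.

### Sex-stratified genetic association and heterogeneity

Association fits are additive-model OLS of the logged metabolite on the
effect-allele dosage plus age, BMI and batch indicators, run separately in
men and women. SNPs are excluded when the folded minor-allele frequency is
below 1% in either stratum or the imputation quality rsq is below 0.4;
both boundaries are inclusive (a SNP exactly at maf = 0.01 or rsq = 0.4 is
kept) since the exclusion rule is phrased as "lower than".

Equality of the two stratum coefficients is tested with

    z = (beta_men - beta_women) / sqrt(SE_men^2 + SE_women^2),
    p = 2 * (1 - Phi(|z|)),

the standard large-sample test for comparing regression coefficients
across independent samples. No covariance term is needed because the
strata are disjoint by construction. Identical betas give p = 1 exactly.
The genome-wide scan applies this to every kept SNP x metabolite pair with
significance at 5e-8 divided by the number of metabolite phenotypes.

Per-stratum estimates from several cohorts are pooled by inverse-variance
meta-analysis and the heterogeneity test is then applied to the two pooled
estimates. A heterogeneity signal replicates when the stratum with the
larger absolute effect matches the discovery cohort and the replication
heterogeneity p is below 0.05/k (k = SNPs carried forward); effect alleles
are harmonized first (a flip negates both betas and z, leaving p and the
larger-|beta| stratum unchanged). The variance explained by a SNP is the
difference of coefficients of determination between the covariate model
with and without the SNP, on the identical complete-case sample, which is
non-negative for nested OLS.

## Quality control chain

1. **Metrics.** Per metabolite: (i) the coefficient of variation of each
   plate QC sample over its replicates, averaged over all QC samples and
   batches; (ii) the percentage of study samples with an observed value
   above the limit of detection; (iii) the Pearson correlation between
   first and duplicate measurements of re-measured samples.
2. **Filters.** Keep metabolites with mean CV < 25%, >= 90% of samples
   above LOD, and duplicate r > 0.5. The CV and duplicate-r comparisons are
   strict and the LOD percentage inclusive, matching how the criteria are
   phrased.
3. **Batch adjustment.** Concentrations in batch b are divided by
   (batch-b QC mean / grand QC mean) per metabolite. The grand QC mean is
   the unweighted mean of batch means and is invariant under adjustment;
   after adjustment all batch QC means are equal.
4. **Outlier removal**, separately per sex stratum: columns standardized,
   rows projected onto the unit sphere, robust Mahalanobis distances from a
   minimum-covariance-determinant location/scatter fit (scikit-learn
   MinCovDet, fixed random state — a deterministic stand-in for
   robust-principal-components distance estimation; the contract is only
   "robust location/scatter, then Mahalanobis"). The cutoff is
   mean(d) + 3*Var(d) by default, with a `spread="sd"` switch for
   mean + 3*SD. The unit-sphere projection concentrates inlier distances
   tightly, which is what makes the variance-based cutoff discriminating;
   on planted 10-SD contamination it recovers all outliers with no false
   positives in our checks.
5. **Imputation.** Below-LOD entries are treated as missing (no LOD/2-style
   substitution) and all missing values are filled by chained per-column
   regression (scikit-learn IterativeImputer, 10 sweeps, seeded — a
   deterministic analogue of multiple imputation by chained equations;
   only a single completed dataset is produced). Imputed values are floored
   at half the column minimum so concentrations stay positive. A
   column-median method is available as a fallback.
6. **Log transform.** Natural log, refused on non-positive values and on a
   second application (processing-state flags are monotone).

## Synthetic-data generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream estimator is validated.

* **Cohort.** Ages uniform on 32-81 years; sex-specific BMI, WHR, HDL
  means; lognormal triglycerides; type-2-diabetes, smoking and
  high-alcohol indicators at population-typical rates; random batch
  assignment (3 batches). All ranges are configuration
  (`CohortParams`), not constants.
* **Metabolites.** 131 metabolites in 7 compound classes (14 amino acids,
  24 acylcarnitines, 38 + 38 diacyl/acyl-alkyl phosphatidylcholines, 8
  lysophosphatidylcholines, 8 sphingomyelins, 1 hexose sum). Log-scale
  linear predictor: baseline log-mean + beta_sex*male + age and BMI slopes
  (centered at 55 y / 27 kg/m^2) + additive batch shift + genetic effects;
  residual noise is multivariate normal with exchangeable correlation 0.7
  inside consecutive within-class triples (tight small blocks keep the
  implied partial correlations well above the 0.3 network cutoff, giving
  the network stage recoverable planted structure) and zero between blocks.
  Sex-effect magnitudes are class-typical (amino acids, acylcarnitines,
  lysoPCs and hexoses higher in men; PCs and sphingomyelins higher in
  women) with named members (e.g. a glycine analogue at beta_sex = -0.13)
  at effect sizes reported for large population panels. LOD defaults to
  three residual SDs below the baseline mean (~0.1% censoring); censored
  entries are emitted as missing plus a below-LOD flag, leaving the
  substitution policy to the QC stage. Plate QC samples (3 per batch, 5
  replicates, ~8% CV) and 40 duplicate re-measurements are emitted per
  dataset.
* **Genotypes.** Hardy-Weinberg Binomial(2, maf) effect-allele counts;
  imputed dosages shrink the genotype toward its expectation so the
  dosage-variance ratio matches the configured rsq (rsq = 1 reproduces
  hard calls). Per-allele effects are sex-specific, act through the true
  genotype, and are centered within each sex stratum so the panel's
  configured beta_sex remains the marginal male-female difference
  (centering shifts each stratum by a constant and therefore leaves
  within-stratum dosage slopes untouched).
* **Scenarios.** `default` (620 samples, 131 metabolites, a 3-SNP locus
  with female-dominant glycine effects), `null` (all effects zero),
  `qc163` (163 metabolites engineered so exactly 131 survive QC: 11 fail
  on CV, 11 on LOD coverage, 10 on duplicate correlation), and `gwas`
  (1809 samples split 912/897). Fixture sets round-trip losslessly through
  the TSV readers and carry a JSON manifest of the planted truth.

**What the generator does not emulate:** raw spectra or chromatography,
genotype calling/imputation mechanics, linkage disequilibrium between
SNPs, non-Gaussian concentration tails, informative missingness beyond LOD
censoring, or covariate-dependent batch effects. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not robustness to every artefact of real kit data.

## Numerical choices and problem sizes

* Seeds: every stochastic routine takes an explicit seed; identical seeds
  give byte-identical outputs. Scenario seeds are spawned via
  `numpy.random.SeedSequence`.
* The validation suite exercises desk-scale problem sizes chosen to give
  comfortable statistical power while keeping runs quick: parameter
  recovery at n = 1800-3000, heterogeneity-test calibration on 10^4
  simulated null scans at 500 samples per stratum, outlier recovery at 510
  samples x 20 metabolites per stratum, network-oracle equivalence on 100
  random panels of up to 10 metabolites.
* Cohort-scale headline counts from population studies (e.g. how many of
  131 metabolites reach panel-wide significance, or the exact number of
  network edges at a given cutoff) depend on the real data's effect-size
  and correlation spectrum and are not asserted on synthetic data; the
  suite asserts planted-truth recovery and analytic identities instead.
* Degenerate inputs fail loudly: empty strata, constant metabolites or
  dosages, all-missing columns, singular correlation matrices and
  non-positive concentrations all raise errors naming the offender rather
  than propagating NaNs.

## Known limitations

* The robust-distance stand-in (MinCovDet) and the chained imputer are
  deterministic approximations of the robust-PCA and chained-equations
  tools common in this literature; they honor the same contracts but are
  not drop-in numerical replicas.
* The heterogeneity test is asymptotic; at very small stratum sizes its
  normal approximation (and the scan's significance threshold) becomes
  anti-conservative.
* The GGM stage assumes n > p after QC; there is no sparse estimation
  path beyond the explicit ridge fallback.
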