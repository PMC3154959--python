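# dimorph

Sexual-dimorphism analysis for targeted serum metabolomics panels, with
sex-stratified genetic association.

Population studies show that men and women differ systematically in serum
metabolite concentrations — amino acids and acylcarnitines tend to run
higher in men, most phosphatidylcholines and sphingomyelins higher in women
— and that the *genetic* control of some metabolites (such as glycine at
urea-cycle loci) differs between the sexes as well. `dimorph` packages the
full analysis chain such a study needs, for epidemiologists and statistical
geneticists working with kit-based metabolite panels and SNP dosage data:

* **`metabo_qc`** — panel quality control: per-metabolite QC-replicate CV,
  %-above-LOD and duplicate-correlation metrics with the standard
  CV < 25% / >= 90% > LOD / r > 0.5 filters; QC-sample-based batch
  adjustment; sex-stratified robust multivariate outlier removal
  (standardize, project to the unit sphere, robust Mahalanobis distances,
  cutoff mean + 3·Var); chained-regression imputation; log transform.
* **`sex_effects`** — per-metabolite OLS of log concentration on sex
  (male = 1) plus covariate models (age/BMI base, WHR, lipids, T2D,
  lifestyle), the relative difference
  Δ = 100·(mean_men − mean_women)/mean_men, Bonferroni thresholds, a
  sign-consistent replication rule, inverse-variance fixed-effect
  meta-analysis, and two-component PLS scores of the global male/female
  separation.
* **`ggm_network`** — the covariate-adjusted full-order partial-correlation
  network (Gaussian graphical model): r_ij = −P_ij/√(P_ii·P_jj) from the
  inverse residual correlation matrix, |r| ≥ cutoff edge rule,
  non-singleton connected components, cutoff sweeps, annotated
  GraphML/GML export.
* **`sexdiff_gwas`** — sex-stratified additive-model SNP association with
  per-stratum MAF and imputation-quality filters, the beta-difference
  heterogeneity test z = (β_men − β_women)/√(SE_men² + SE_women²) with
  two-sided normal p, genome-wide scans at 5×10⁻⁸/n_phenotypes,
  inverse-variance meta-analysis per stratum with combined heterogeneity,
  SNP explained-variance (ΔR²), allele-harmonized replication rules, and
  Manhattan/QQ table export.
* **`synthdata`** — a seeded generator of cohorts, correlated log-normal
  metabolite panels (with batch shifts, LOD censoring, QC replicates and
  duplicate re-measurements) and Hardy–Weinberg SNPs with sex-specific
  per-allele effects, so the whole pipeline is testable end to end with no
  external data.

## Worked example

```python
import numpy as np
from dimorph import synthdata, metabo_qc, sex_effects, ggm_network, sexdiff_gwas

# 1. simulate a cohort with a planted sex-dimorphic glycine locus
cohort = synthdata.generate_cohort(n_male=912, n_female=897, seed=11)
panel = synthdata.default_panel()
geno, genetic = synthdata.generate_genotypes(
    cohort, synthdata.GLYCINE_LOCUS_SNPS, seed=12)
mets = synthdata.generate_metabolites(
    cohort, panel, seed=13, genetic_effects=genetic)

# 2. quality control: metrics -> filters -> batch adjustment -> outliers
#    -> imputation -> log transform
report = metabo_qc.qc_metrics(mets)
kept = metabo_qc.apply_qc_filters(report)
mets = mets.subset_metabolites(kept)
mets = metabo_qc.qc_normalize_batches(mets)
mets = metabo_qc.impute_missing(mets, seed=14)
outliers = metabo_qc.detect_outliers(mets, cohort)
mets = mets.drop_samples(outliers["male"] + outliers["female"])
delta_gly = sex_effects.delta_table(cohort, mets)["Gly"]
logged = metabo_qc.log_transform(mets)

# 3. per-metabolite sex effects
rec = sex_effects.fit_sex_effect("Gly", cohort, logged)
thr = sex_effects.bonferroni_threshold(0.05, len(kept))
table = sex_effects.sex_effect_table(cohort, logged)
print(f"glycine: beta_sex = {rec.beta_sex:+.3f} (SE {rec.se:.3f}), "
      f"p = {rec.p:.2e}, Delta = {delta_gly:+.1f}%")
print(f"{(table['p'] < thr).sum()}/{len(table)} metabolites sex-dimorphic "
      f"at p < {thr:.1e}")

# 4. partial-correlation network
cov = cohort.set_index("sample_id").loc[logged.values.index, ["age", "bmi"]]
cov["sex_male"] = (cohort.set_index("sample_id")["sex"] == "male") * 1.0
pcor = ggm_network.partial_correlation_matrix(logged.values, cov)
net = ggm_network.build_ggm(pcor, cutoff=0.3, classes=logged.classes)
n_groups, _ = ggm_network.nonsingleton_groups(net)
print(f"GGM: {net.n_edges} of {131*130//2} pairs with |r| >= 0.3, "
      f"{n_groups} non-singleton groups")

# 5. sex-stratified scan and heterogeneity test
scan = sexdiff_gwas.genomewide_scan(geno, logged.subset_metabolites(
    ["Gly", "Ser", "Val", "xLeu", "C18", "H1"]), cohort)
top = scan.loc[scan["p"].idxmin()]
print(f"top heterogeneity hit: {top.snp} x {top.metabolite}, "
      f"beta_men = {top.beta_men:+.3f}, beta_women = {top.beta_women:+.3f}, "
      f"p = {top.p:.2e}")
```

Output:

```
glycine: beta_sex = -0.149 (SE 0.017), p = 5.60e-19, Delta = -17.8%
115/131 metabolites sex-dimorphic at p < 3.8e-04
GGM: 125 of 8515 pairs with |r| >= 0.3, 45 non-singleton groups
top heterogeneity hit: snp_top x Gly, beta_men = -0.060, beta_women = -0.172, p = 7.90e-06
```

The fitted glycine sex effect (−0.149, higher in women) recovers the
planted −0.13 within sampling error, and Δ = −17.8% says the mean male
concentration is ~18% below the female mean. Of the 8515 metabolite pairs,
only ~1.5% show a direct (partial) correlation above 0.3 — the network is
sparse, and its connected groups track the planted within-class correlation
blocks. The scan's strongest sex-heterogeneity signal is the planted locus:
the per-allele effect on log glycine is nearly three times larger in women
than in men. (At this single-cohort sample size the heterogeneity p-value
is suggestive rather than genome-wide significant — in the scan framework
significance is declared at 5×10⁻⁸ divided by the number of phenotypes.)

A thin CLI wraps the same stages:

```bash
dimorph simulate --scenario gwas --seed 1 --out data/
dimorph qc --in data/ --out qcd/
dimorph sex-effects --cohort qcd/ --model base --out sex_effects.tsv
dimorph ggm --in qcd/ --cutoff 0.3 --out network.graphml
dimorph scan --in qcd/ --out scan/
```

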