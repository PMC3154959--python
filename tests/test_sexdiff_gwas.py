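"""Sex-stratified association, heterogeneity test, meta-analysis,
replication-rule and export tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimorph import metabo_qc
from dimorph.datatypes import GenotypeMatrix
from dimorph.sexdiff_gwas import (
    HetTestRecord,
    beta_difference_test,
    combined_heterogeneity,
    export_scan_tables,
    filter_snps,
    fit_additive_model,
    flip_effect_allele,
    genomewide_scan,
    inverse_variance_meta,
    replication_check,
    snp_explained_variance,
    stratified_assoc,
)
from dimorph.synthdata import SnpSpec, generate_cohort, generate_genotypes, \
    generate_metabolites

from conftest import make_panel


def _geno(dosage_dict, index, rsq=None):
    dosages = pd.DataFrame(dosage_dict, index=index)
    info = pd.DataFrame(
        {"effect_allele": "A",
         "rsq": [1.0 if rsq is None else rsq[s] for s in dosages.columns]},
        index=dosages.columns,
    )
    return GenotypeMatrix(dosages=dosages, snp_info=info)


class TestFilterSnps:
    @staticmethod
    def _gm(maf_male, maf_female, rsq):
        dosages = pd.DataFrame({"s": [0.0, 1.0]}, index=["a", "b"])
        info = pd.DataFrame({"effect_allele": ["A"], "rsq": [rsq]}, index=["s"])
        maf = pd.DataFrame({"male": [maf_male], "female": [maf_female]},
                           index=["s"])
        return GenotypeMatrix(dosages=dosages, snp_info=info, stratum_maf=maf)

    def test_rare_in_one_stratum_excluded(self):
        assert filter_snps(self._gm(0.05, 0.005, 0.9)) == []

    def test_rsq_boundary_inclusive(self):
        assert filter_snps(self._gm(0.2, 0.2, 0.39)) == []
        assert filter_snps(self._gm(0.2, 0.2, 0.40)) == ["s"]

    def test_maf_boundary_inclusive(self):
        assert filter_snps(self._gm(0.01, 0.2, 0.9)) == ["s"]

    def test_all_passing_identity(self):
        cohort = generate_cohort(200, 200, seed=51)
        snps = [SnpSpec(f"s{i}", maf=0.3, target="A", rsq=0.9) for i in range(4)]
        g, _ = generate_genotypes(cohort, snps, 52)
        assert filter_snps(g) == [f"s{i}" for i in range(4)]


class TestStratifiedAssoc:
    def test_planted_stratum_betas_recovered_within_3_se(self):
        cohort = generate_cohort(912, 897, seed=53)
        spec = SnpSpec("rs", maf=0.33, target="Gly", beta_men=-0.067,
                       beta_women=-0.206, rsq=0.99)
        g, eff = generate_genotypes(cohort, [spec], 54)
        m = metabo_qc.log_transform(
            generate_metabolites(cohort, make_panel(["Gly"]), 55,
                                 genetic_effects=eff)
        )
        men = stratified_assoc("rs", "Gly", g, m, cohort, "male")
        women = stratified_assoc("rs", "Gly", g, m, cohort, "female")
        assert abs(men.beta - (-0.067)) < 3 * men.se
        assert abs(women.beta - (-0.206)) < 3 * women.se
        assert men.n + women.n == 1809

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        cohort = generate_cohort(300, 300, seed=56)
        spec = SnpSpec("rs", maf=0.3, target="A", beta_men=0.1, beta_women=0.1)
        g, eff = generate_genotypes(cohort, [spec], 57)
        m = metabo_qc.log_transform(
            generate_metabolites(cohort, make_panel(["A"]), 58,
                                 genetic_effects=eff)
        )
        ours = stratified_assoc("rs", "A", g, m, cohort, "male",
                                include_batch=False)
        men = cohort[cohort["sex"] == "male"].set_index("sample_id")
        X = sm.add_constant(
            pd.DataFrame(
                {"dosage": g.dosages.loc[men.index, "rs"],
                 "age": men["age"], "bmi": men["bmi"]}
            )
        )
        ref = sm.OLS(m.values.loc[men.index, "A"], X).fit()
        assert ours.beta == pytest.approx(ref.params["dosage"], rel=1e-10)
        assert ours.se == pytest.approx(ref.bse["dosage"], rel=1e-10)
        assert ours.p == pytest.approx(ref.pvalues["dosage"], rel=1e-8)

    def test_null_snp_p_uniform(self):
        # rejection rate of the per-stratum test at alpha=0.05 under the null
        rng = np.random.default_rng(59)
        n, hits, reps = 400, 0, 400
        age = rng.uniform(30, 80, n)
        for _ in range(reps):
            dosage = rng.binomial(2, 0.3, n).astype(float)
            y = 0.01 * age + rng.standard_normal(n)
            _, _, _, p = fit_additive_model(y, dosage, age[:, None])
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.075

    def test_constant_dosage_errors(self):
        cohort = generate_cohort(50, 50, seed=60)
        m = metabo_qc.log_transform(
            generate_metabolites(cohort, make_panel(["A"]), 61)
        )
        g = _geno({"rs": np.zeros(100)}, pd.Index(cohort["sample_id"]))
        with pytest.raises(ValueError, match="constant"):
            stratified_assoc("rs", "A", g, m, cohort, "male")


class TestBetaDifferenceTest:
    @pytest.mark.parametrize(
        "bm,sm,bw,sw,expected,rel",
        [
            (-0.067, 0.012, -0.206, 0.016, 3.65e-12, 0.05),
            (-0.078, 0.013, -0.22, 0.017, 3.24e-11, 0.05),
            (-0.115, 0.031, -0.229, 0.043, 0.03151, 0.001),
        ],
    )
    def test_printed_worked_examples(self, bm, sm, bw, sw, expected, rel):
        _, p = beta_difference_test(bm, sm, bw, sw)
        assert p == pytest.approx(expected, rel=rel)

    def test_equal_betas_give_exactly_one(self):
        z, p = beta_difference_test(-0.113, 0.033, -0.113, 0.047)
        assert z == 0.0 and p == 1.0

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(-1, 1), st.floats(0.001, 1),
        st.floats(-1, 1), st.floats(0.001, 1),
    )
    def test_antisymmetry_under_stratum_swap(self, bm, sm, bw, sw):
        z1, p1 = beta_difference_test(bm, sm, bw, sw)
        z2, p2 = beta_difference_test(bw, sw, bm, sm)
        assert z2 == pytest.approx(-z1, abs=1e-12)
        assert p2 == pytest.approx(p1, rel=1e-9)

    def test_non_positive_se_rejected(self):
        with pytest.raises(ValueError):
            beta_difference_test(0.1, 0.0, 0.2, 0.1)


class TestGenomewideScan:
    @staticmethod
    def _dataset(seed, betas=((-0.078, -0.22),)):
        cohort = generate_cohort(450, 450, seed=seed)
        snps = [
            SnpSpec(f"rs{i}", maf=0.3, target="Gly", beta_men=bm,
                    beta_women=bw, rsq=0.95)
            for i, (bm, bw) in enumerate(betas)
        ]
        g, eff = generate_genotypes(cohort, snps, seed + 1)
        panel = make_panel(["Gly", "Val"], beta_sex=[-0.13, 0.14])
        m = metabo_qc.log_transform(
            generate_metabolites(cohort, panel, seed + 2, genetic_effects=eff)
        )
        return cohort, g, m

    def test_planted_heterogeneous_snp_is_top_hit(self):
        cohort, g, m = self._dataset(
            62, betas=((-0.078, -0.22), (0.0, 0.0), (0.1, 0.1))
        )
        scan = genomewide_scan(g, m, cohort)
        assert len(scan) == 3 * 2
        top = scan.loc[scan["p"].idxmin()]
        assert (top["snp"], top["metabolite"]) == ("rs0", "Gly")
        assert scan.attrs["significance_threshold"] == pytest.approx(2.5e-8)

    def test_zero_snps_after_filters_gives_empty_result(self):
        cohort, g, m = self._dataset(63)
        g.snp_info["rsq"] = 0.2
        scan = genomewide_scan(g, m, cohort)
        assert len(scan) == 0

    def test_failed_pair_excluded_with_reason(self):
        cohort, g, m = self._dataset(64)
        const = pd.Series(
            np.where(cohort["sex"].to_numpy() == "male", 0.5, 1.0),
            index=g.dosages.index,
        )
        g.dosages["rs_const"] = const  # constant within each stratum
        g.snp_info.loc["rs_const"] = {"effect_allele": "A", "rsq": 1.0,
                                      "chrom": None, "pos": None,
                                      "target": "Gly"}
        g.stratum_maf.loc["rs_const"] = [0.25, 0.25]
        scan = genomewide_scan(g, m, cohort)
        bad = scan[scan["snp"] == "rs_const"]
        assert (bad["reason"].str.contains("constant")).all()
        assert bad["p"].isna().all()
        assert not bad["significant"].any()


class TestMeta:
    def test_men_stratum_three_cohort_combination(self):
        beta, se = inverse_variance_meta(
            [(-0.078, 0.013), (-0.081, 0.012), (-0.115, 0.031)]
        )
        assert beta == pytest.approx(-0.082, abs=1e-3)
        assert se == pytest.approx(0.009, abs=1e-3)

    def test_women_stratum_three_cohort_combination(self):
        beta, _ = inverse_variance_meta(
            [(-0.22, 0.017), (-0.225, 0.015), (-0.229, 0.043)]
        )
        assert beta == pytest.approx(-0.223, abs=1e-3)

    def test_single_estimate_identity_and_empty_rejected(self):
        assert inverse_variance_meta([(0.5, 0.1)]) == (0.5, pytest.approx(0.1))
        with pytest.raises(ValueError):
            inverse_variance_meta([])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-1, 1), st.floats(0.01, 1)),
                    min_size=2, max_size=6))
    def test_combined_se_smaller_than_every_input(self, estimates):
        _, se = inverse_variance_meta(estimates)
        assert se < min(s for _, s in estimates)

    def test_combined_heterogeneity_identical_strata_p_one(self):
        out = combined_heterogeneity([(0.1, 0.02)], [(0.1, 0.02)])
        assert out.p == 1.0

    def test_combined_heterogeneity_two_cohort_men_meta(self):
        out = combined_heterogeneity(
            men=[(-0.043, 0.012), (-0.113, 0.033)],
            women=[(-0.172, 0.016), (-0.113, 0.047)],
        )
        assert out.beta_men == pytest.approx(-0.051, abs=1e-3)

    def test_single_cohort_meta_reduces_to_per_cohort_test(self):
        direct = beta_difference_test(-0.067, 0.012, -0.206, 0.016)
        via_meta = combined_heterogeneity([(-0.067, 0.012)], [(-0.206, 0.016)])
        assert (via_meta.z, via_meta.p) == pytest.approx(direct)


class TestExplainedVariance:
    def test_null_snp_near_zero(self):
        cohort = generate_cohort(500, 500, seed=65)
        g, eff = generate_genotypes(
            cohort, [SnpSpec("rs", maf=0.3, target="A")], 66
        )
        m = metabo_qc.log_transform(
            generate_metabolites(cohort, make_panel(["A"]), 67)
        )
        r2 = snp_explained_variance("rs", "A", g, m, cohort)
        assert 0 <= r2 < 5.0 / 1000

    def test_planted_effect_recovered(self):
        # beta chosen so the SNP explains ~5% of the residual variance:
        # var(beta*g)/total = beta^2*2maf(1-maf) / (beta^2*2maf(1-maf)+sd^2)
        cohort = generate_cohort(1500, 1500, seed=68)
        beta = np.sqrt(0.05 / 0.95 * 0.25**2 / (2 * 0.3 * 0.7))
        g, eff = generate_genotypes(
            cohort,
            [SnpSpec("rs", maf=0.3, target="A", beta_men=beta,
                     beta_women=beta)],
            69,
        )
        m = metabo_qc.log_transform(
            generate_metabolites(cohort, make_panel(["A"], log_sd=0.25), 70,
                                 genetic_effects=eff)
        )
        r2 = snp_explained_variance("rs", "A", g, m, cohort)
        assert r2 == pytest.approx(0.05, abs=0.015)

    def test_snp_collinear_with_covariate_explains_nothing(self):
        cohort = generate_cohort(200, 200, seed=71)
        m = metabo_qc.log_transform(
            generate_metabolites(cohort, make_panel(["A"]), 72)
        )
        # dosage an affine function of age: no variance left to explain
        age = cohort["age"].to_numpy()
        dose = 2 * (age - age.min()) / np.ptp(age)
        g = _geno({"rs": dose}, pd.Index(cohort["sample_id"]))
        r2 = snp_explained_variance("rs", "A", g, m, cohort,
                                    include_batch=False)
        assert r2 == pytest.approx(0.0, abs=1e-12)


class TestReplicationCheck:
    @staticmethod
    def _rec(bm, sm, bw, sw, snp="snp_coding", ea="C", oa="A"):
        from dimorph.sexdiff_gwas import beta_difference_test

        z, p = beta_difference_test(bm, sm, bw, sw)
        return HetTestRecord(
            snp=snp, metabolite="Gly", beta_men=bm, se_men=sm, beta_women=bw,
            se_women=sw, z=z, p=p,
            larger_stratum="men" if abs(bm) >= abs(bw) else "women",
            effect_allele=ea, other_allele=oa,
        )

    def test_strong_replication_passes_at_bonferroni_8(self):
        disc = self._rec(-0.078, 0.013, -0.22, 0.017)
        rep = self._rec(-0.081, 0.012, -0.225, 0.015)  # p = 1.3e-13
        assert rep.p == pytest.approx(1.3e-13, rel=0.06)
        assert replication_check(disc, rep, k=8)

    def test_consistent_direction_but_weak_p_fails(self):
        disc = self._rec(-0.078, 0.013, -0.22, 0.017)
        rep = self._rec(-0.115, 0.031, -0.229, 0.043)  # p = 0.032
        assert not replication_check(disc, rep, k=8)

    def test_identical_records_below_threshold_replicate(self):
        rec = self._rec(-0.067, 0.012, -0.206, 0.016)
        assert replication_check(rec, rec, k=8)

    def test_allele_flip_invariance(self):
        disc = self._rec(-0.078, 0.013, -0.22, 0.017)
        rep = self._rec(-0.081, 0.012, -0.225, 0.015)
        flipped = flip_effect_allele(rep)
        assert flipped.effect_allele == "A"
        assert replication_check(disc, flipped, k=8) == \
            replication_check(disc, rep, k=8)
        assert flipped.p == rep.p and flipped.z == -rep.z

    def test_unalignable_alleles_error(self):
        disc = self._rec(-0.078, 0.013, -0.22, 0.017, ea="C", oa="A")
        rep = self._rec(-0.081, 0.012, -0.225, 0.015, ea="G", oa="T")
        with pytest.raises(ValueError, match="align"):
            replication_check(disc, rep, k=8)


class TestExportScanTables:
    def test_empty_input_writes_headers_only(self, tmp_path):
        empty = pd.DataFrame(columns=["snp", "metabolite", "chrom", "pos", "p"])
        paths = export_scan_tables(empty, tmp_path)
        man = pd.read_csv(paths["manhattan"], sep="\t")
        qq = pd.read_csv(paths["qq"], sep="\t")
        assert len(man) == 0 and len(qq) == 0
        assert list(qq.columns) == ["expected_neglog10p", "observed_neglog10p"]

    def test_qq_expected_quantiles_and_sorting(self, tmp_path):
        rec = pd.DataFrame(
            {"snp": list("abcd"), "metabolite": "Gly",
             "chrom": [1, 1, 2, 2], "pos": [10, 20, 5, 6],
             "p": [0.5, 0.01, 0.9, 0.2]}
        )
        paths = export_scan_tables(rec, tmp_path)
        qq = pd.read_csv(paths["qq"], sep="\t")
        n = 4
        np.testing.assert_allclose(
            qq["expected_neglog10p"],
            -np.log10((np.arange(1, n + 1) - 0.5) / n),
        )
        obs = qq["observed_neglog10p"].to_numpy()
        assert (np.diff(obs) <= 0).all()  # ascending p = descending -log10
        man = pd.read_csv(paths["manhattan"], sep="\t")
        assert man["chrom"].tolist() == [1, 1, 2, 2]
        assert man["pos"].tolist() == [10, 20, 5, 6]
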