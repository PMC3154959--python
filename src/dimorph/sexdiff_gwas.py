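"""Sex-stratified SNP association and the beta-difference heterogeneity test.

For each SNP x metabolite pair an additive-model OLS is fitted separately in
men and women (log concentration ~ dosage + age + BMI + batch).  Equality of
the two stratum coefficients is tested with the approximately normal
statistic

    z = (beta_men - beta_women) / sqrt(SE_men^2 + SE_women^2),

valid because the strata are disjoint samples.  Per-stratum estimates from
several cohorts are pooled by inverse-variance fixed-effect meta-analysis,
and the heterogeneity test can be applied to the pooled estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SEXES, GenotypeMatrix, MetaboliteMatrix, \
    stratum_allele_frequencies, validate_cohort


# ---------------------------------------------------------------------------
# Low-level OLS


def fit_additive_model(
    y: np.ndarray, dosage: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, int, float]:
    """OLS of y on [1, dosage, covariates]; returns (beta, SE, n, p) for the
    dosage term, with the two-sided p from the t-distribution.

    This is the numerical core of :func:`stratified_assoc`, exposed for
    callers that need many fits without DataFrame overhead.
    """
    y = np.asarray(y, float)
    dosage = np.asarray(dosage, float)
    n = len(y)
    if np.ptp(dosage) == 0:
        raise ValueError("dosage is constant in this stratum")
    cols = [np.ones(n), dosage]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        cols.extend(covariates.T)
    X = np.column_stack(cols)
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as err:
        raise ValueError("collinear design matrix") from err
    beta_hat = XtX_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    dof = n - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough samples for the model")
    sigma2 = float(resid @ resid) / dof
    se = float(np.sqrt(XtX_inv[1, 1] * sigma2))
    beta = float(beta_hat[1])
    p = float(2.0 * stats.t.sf(abs(beta / se), dof)) if se > 0 else float("nan")
    return beta, se, n, p


# ---------------------------------------------------------------------------
# Records


@dataclass
class StratumAssoc:
    """Per-stratum additive-model estimate for one SNP and metabolite."""

    snp: str
    metabolite: str
    stratum: str
    beta: float
    se: float
    n: int
    p: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HetTestRecord:
    """Sex-heterogeneity test result for one SNP and metabolite."""

    snp: str
    metabolite: str
    beta_men: float
    se_men: float
    beta_women: float
    se_women: float
    z: float
    p: float
    larger_stratum: str
    effect_allele: str | None = None
    other_allele: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# SNP filters


def filter_snps(
    g: GenotypeMatrix,
    cohort: pd.DataFrame | None = None,
    maf_min: float = 0.01,
    rsq_min: float = 0.4,
) -> list[str]:
    """SNPs kept for analysis: minor-allele frequency >= maf_min in *both*
    sex strata and imputation quality rsq >= rsq_min (inclusive boundaries).
    """
    maf = g.stratum_maf
    if maf is None:
        if cohort is None:
            raise ValueError("per-stratum MAFs missing; pass the cohort")
        maf = stratum_allele_frequencies(g.dosages, cohort)
    keep = (
        (maf["male"] >= maf_min)
        & (maf["female"] >= maf_min)
        & (g.snp_info["rsq"] >= rsq_min)
    )
    return list(g.dosages.columns[keep.reindex(g.dosages.columns).fillna(False)])


# ---------------------------------------------------------------------------
# Stratified association


def _stratum_design(
    cohort: pd.DataFrame, covariates: Sequence[str], include_batch: bool
) -> pd.DataFrame:
    X = cohort[list(covariates)].astype(float)
    if include_batch and cohort["batch"].nunique() > 1:
        X = pd.concat(
            [X, pd.get_dummies(cohort["batch"], prefix="batch", drop_first=True)
             .astype(float)],
            axis=1,
        )
    return X


def stratified_assoc(
    snp: str,
    metabolite: str,
    g: GenotypeMatrix,
    m: MetaboliteMatrix,
    cohort: pd.DataFrame,
    stratum: str,
    covariates: Sequence[str] = ("age", "bmi"),
    include_batch: bool = True,
) -> StratumAssoc:
    """Additive-model OLS of the logged metabolite on the SNP dosage within
    one sex stratum, adjusted for age, BMI and batch."""
    if stratum not in SEXES:
        raise ValueError(f"stratum must be one of {SEXES}")
    if not m.logged:
        raise ValueError("metabolite matrix must be log-transformed first")
    validate_cohort(cohort)
    sub = cohort[cohort["sex"] == stratum].set_index("sample_id")
    ids = sub.index.intersection(m.values.index).intersection(g.dosages.index)
    y = m.values.loc[ids, metabolite]
    keep = y.notna()
    ids = ids[keep.to_numpy()]
    if len(ids) == 0:
        raise ValueError(f"no usable samples in stratum {stratum!r}")
    X = _stratum_design(sub.loc[ids].reset_index(), covariates, include_batch)
    beta, se, n, p = fit_additive_model(
        m.values.loc[ids, metabolite].to_numpy(),
        g.dosages.loc[ids, snp].to_numpy(),
        X.to_numpy(),
    )
    return StratumAssoc(snp, metabolite, stratum, beta, se, n, p)


# ---------------------------------------------------------------------------
# Heterogeneity test


def beta_difference_test(
    beta_men: float, se_men: float, beta_women: float, se_women: float
) -> tuple[float, float]:
    """z = (beta_men - beta_women)/sqrt(SE_men^2 + SE_women^2) and its
    two-sided normal p-value.  Equal betas give z = 0, p = 1 exactly."""
    if se_men <= 0 or se_women <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_men - beta_women) / float(np.hypot(se_men, se_women))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def genomewide_scan(
    g: GenotypeMatrix,
    m: MetaboliteMatrix,
    cohort: pd.DataFrame,
    covariates: Sequence[str] = ("age", "bmi"),
    include_batch: bool = True,
    alpha: float = 5e-8,
    maf_min: float = 0.01,
    rsq_min: float = 0.4,
) -> pd.DataFrame:
    """Heterogeneity test for every kept SNP x metabolite pair.

    The significance threshold is alpha Bonferroni-corrected for the number
    of metabolite phenotypes.  Pairs whose stratified fit fails (e.g.
    constant dosage in a stratum) appear with NaN statistics and a ``reason``
    column instead of raising.
    """
    snps = filter_snps(g, cohort, maf_min=maf_min, rsq_min=rsq_min)
    mets = m.metabolites
    threshold = alpha / max(len(mets), 1)
    rows = []
    for snp in snps:
        for met in mets:
            row = {"snp": snp, "metabolite": met}
            try:
                men = stratified_assoc(
                    snp, met, g, m, cohort, "male", covariates, include_batch
                )
                women = stratified_assoc(
                    snp, met, g, m, cohort, "female", covariates, include_batch
                )
                z, p = beta_difference_test(men.beta, men.se, women.beta, women.se)
                row.update(
                    beta_men=men.beta, se_men=men.se, n_men=men.n,
                    beta_women=women.beta, se_women=women.se, n_women=women.n,
                    z=z, p=p,
                    larger_stratum="men" if abs(men.beta) >= abs(women.beta)
                    else "women",
                    significant=p < threshold,
                    reason="",
                )
            except ValueError as err:
                row.update(
                    beta_men=np.nan, se_men=np.nan, n_men=0,
                    beta_women=np.nan, se_women=np.nan, n_women=0,
                    z=np.nan, p=np.nan, larger_stratum="",
                    significant=False, reason=str(err),
                )
            rows.append(row)
    cols = ["snp", "metabolite", "beta_men", "se_men", "n_men", "beta_women",
            "se_women", "n_women", "z", "p", "larger_stratum", "significant",
            "reason"]
    out = pd.DataFrame(rows, columns=cols)
    out.attrs["significance_threshold"] = threshold
    return out


# ---------------------------------------------------------------------------
# Meta-analysis


def inverse_variance_meta(
    estimates: Iterable[tuple[float, float]]
) -> tuple[float, float]:
    """Fixed-effect pooling of (beta, SE) estimates with weights 1/SE^2.

    Returns (combined beta, combined SE = 1/sqrt(sum of weights))."""
    estimates = list(estimates)
    if not estimates:
        raise ValueError("need at least one estimate")
    betas = np.array([b for b, _ in estimates], float)
    ses = np.array([s for _, s in estimates], float)
    if (ses <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    return float(np.sum(w * betas) / np.sum(w)), float(1.0 / np.sqrt(np.sum(w)))


@dataclass
class CombinedHet:
    """Cross-cohort pooled per-stratum estimates and their heterogeneity test."""

    beta_men: float
    se_men: float
    beta_women: float
    se_women: float
    z: float
    p: float


def combined_heterogeneity(
    men: Iterable[tuple[float, float]], women: Iterable[tuple[float, float]]
) -> CombinedHet:
    """Meta-analyze each stratum across cohorts, then apply the
    beta-difference test to the two pooled estimates."""
    bm, sm = inverse_variance_meta(men)
    bw, sw = inverse_variance_meta(women)
    z, p = beta_difference_test(bm, sm, bw, sw)
    return CombinedHet(bm, sm, bw, sw, z, p)


# ---------------------------------------------------------------------------
# Explained variance, replication, export


def snp_explained_variance(
    snp: str,
    metabolite: str,
    g: GenotypeMatrix,
    m: MetaboliteMatrix,
    cohort: pd.DataFrame,
    stratum: str | None = None,
    covariates: Sequence[str] = ("age", "bmi"),
    include_batch: bool = True,
) -> float:
    """R^2 attributable to the SNP: difference of the coefficients of
    determination of the covariate model with and without the SNP, computed
    on the same complete-case sample (hence >= 0 up to numerical noise)."""
    if not m.logged:
        raise ValueError("metabolite matrix must be log-transformed first")
    validate_cohort(cohort)
    sub = cohort if stratum is None else cohort[cohort["sex"] == stratum]
    sub = sub.set_index("sample_id")
    ids = sub.index.intersection(m.values.index).intersection(g.dosages.index)
    y = m.values.loc[ids, metabolite]
    ids = ids[y.notna().to_numpy()]
    y = m.values.loc[ids, metabolite].to_numpy()
    X = _stratum_design(sub.loc[ids].reset_index(), covariates, include_batch)
    C = np.column_stack([np.ones(len(ids)), X.to_numpy()])
    dose = g.dosages.loc[ids, snp].to_numpy()[:, None]

    def rsq(design):
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        tss = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(resid @ resid) / tss

    r2_without = rsq(C)
    r2_with = rsq(np.hstack([C, dose]))
    return max(r2_with - r2_without, 0.0)


def flip_effect_allele(rec: HetTestRecord) -> HetTestRecord:
    """Re-express a record on the opposite allele: dosage -> 2 - dosage flips
    both stratum betas; z flips; p and the larger-|beta| stratum are
    unchanged."""
    return HetTestRecord(
        snp=rec.snp,
        metabolite=rec.metabolite,
        beta_men=-rec.beta_men,
        se_men=rec.se_men,
        beta_women=-rec.beta_women,
        se_women=rec.se_women,
        z=-rec.z,
        p=rec.p,
        larger_stratum=rec.larger_stratum,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
    )


def replication_check(
    discovery: HetTestRecord, replication: HetTestRecord, k: int
) -> bool:
    """A discovery heterogeneity signal replicates iff the stratum with the
    larger absolute effect is the same in the replication cohort and the
    replication heterogeneity p is below 0.05/k (k = SNPs carried forward).

    Alleles are harmonized first; a replication record on an allele that is
    neither the discovery effect allele nor its stated alternative raises.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rep = replication
    if (
        discovery.effect_allele is not None
        and rep.effect_allele is not None
        and rep.effect_allele != discovery.effect_allele
    ):
        if rep.other_allele == discovery.effect_allele:
            rep = flip_effect_allele(rep)
        else:
            raise ValueError(
                f"cannot align alleles for {rep.snp}: replication "
                f"{rep.effect_allele}/{rep.other_allele} vs discovery "
                f"{discovery.effect_allele}"
            )
    return bool(
        rep.larger_stratum == discovery.larger_stratum and rep.p < 0.05 / k
    )


def export_scan_tables(records: pd.DataFrame, outdir) -> dict[str, Path]:
    """Write Manhattan- and QQ-plot source tables for a scan result frame.

    ``manhattan.tsv`` holds (snp, metabolite, chrom, pos, p) sorted by
    chromosome/position when available, else by p.  ``qq.tsv`` holds the
    uniform order-statistic expected quantiles -log10((i-0.5)/N) against the
    observed -log10 p sorted ascending in p.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec = records.dropna(subset=["p"]) if len(records) else records
    man_cols = ["snp", "metabolite", "chrom", "pos", "p"]
    man = rec.reindex(columns=man_cols)
    if len(man) and man[["chrom", "pos"]].notna().all().all():
        man = man.sort_values(["chrom", "pos"])
    else:
        man = man.sort_values("p") if len(man) else man
    man_path = outdir / "manhattan.tsv"
    man.to_csv(man_path, sep="\t", index=False)

    p_sorted = np.sort(rec["p"].to_numpy()) if len(rec) else np.array([])
    n = len(p_sorted)
    qq = pd.DataFrame(
        {
            "expected_neglog10p": -np.log10((np.arange(1, n + 1) - 0.5) / n)
            if n else [],
            "observed_neglog10p": -np.log10(p_sorted) if n else [],
        }
    )
    qq_path = outdir / "qq.tsv"
    qq.to_csv(qq_path, sep="\t", index=False)
    return {"manhattan": man_path, "qq": qq_path}
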