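"""Core in-memory containers for the sex-dimorphism pipeline.

A cohort is a plain :class:`pandas.DataFrame` with one row per sample and the
columns listed in :data:`COHORT_COLUMNS` (``validate_cohort`` enforces the
schema).  Metabolite and genotype panels carry enough side information (LOD,
QC replicates, duplicate re-measurements, imputation quality) that they get
small dataclass wrappers around their DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Required cohort columns and their pandas dtypes (kind letter).
COHORT_COLUMNS = {
    "sample_id": "O",
    "sex": "O",  # "male" / "female"
    "age": "f",
    "bmi": "f",
    "whr": "f",
    "batch": "i",
    "hdl": "f",
    "ldl": "f",
    "triglycerides": "f",
    "t2d": "b",
    "smoker": "b",
    "high_alcohol": "b",
}

SEXES = ("male", "female")


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort schema and invariants; returns the frame unchanged.

    Raises
    ------
    ValueError
        on missing columns, duplicated sample ids, non-positive age/BMI or
        unknown sex labels.
    """
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")
    if cohort["sample_id"].duplicated().any():
        dup = cohort.loc[cohort["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample_id: {dup!r}")
    bad_sex = set(cohort["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
    if len(cohort) and ((cohort["age"] <= 0).any() or (cohort["bmi"] <= 0).any()):
        raise ValueError("age and bmi must be positive")
    return cohort


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites concentration matrix with QC side information.

    Attributes
    ----------
    values : DataFrame
        Concentrations (uM), indexed by sample_id, one column per metabolite.
        Missing entries are NaN; entries censored at the limit of detection
        are NaN *and* flagged in ``below_lod``.
    lod : Series
        Per-metabolite limit of detection.
    classes : Series
        Per-metabolite compound-class label (amino acid, acylcarnitine, ...).
    qc : DataFrame
        Long table of QC-sample replicate measurements with columns
        ``batch``, ``qc_id``, ``replicate`` and one column per metabolite.
    duplicates : DataFrame
        Second measurement of re-measured samples (subset of ``values.index``,
        same columns) used for the duplicate-correlation QC criterion.
    batch : Series
        Per-sample batch label, aligned with ``values.index``.
    below_lod : DataFrame
        Boolean censoring flags, same shape as ``values``.
    normalized, imputed, logged : bool
        Processing-state flags; monotone (an operation never unsets one).
    """

    values: pd.DataFrame
    lod: pd.Series
    classes: pd.Series
    qc: pd.DataFrame
    duplicates: pd.DataFrame
    batch: pd.Series
    below_lod: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    normalized: bool = False
    imputed: bool = False
    logged: bool = False

    def __post_init__(self) -> None:
        if self.below_lod is None:
            self.below_lod = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if not self.logged and (self.values < 0).any().any():
            raise ValueError("concentrations must be non-negative")
        unknown = self.duplicates.index.difference(self.values.index)
        if len(unknown):
            raise ValueError(
                f"duplicate measurements reference unknown samples: {list(unknown[:3])}"
            )

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def subset_metabolites(self, keep: list[str]) -> "MetaboliteMatrix":
        keep = list(keep)
        return replace(
            self,
            values=self.values[keep].copy(),
            lod=self.lod[keep].copy(),
            classes=self.classes[keep].copy(),
            qc=self.qc[["batch", "qc_id", "replicate"] + keep].copy(),
            duplicates=self.duplicates[keep].copy(),
            below_lod=self.below_lod[keep].copy(),
        )

    def drop_samples(self, sample_ids) -> "MetaboliteMatrix":
        keep = self.values.index.difference(pd.Index(sample_ids))
        keep = self.values.index[self.values.index.isin(keep)]  # preserve order
        return replace(
            self,
            values=self.values.loc[keep].copy(),
            below_lod=self.below_lod.loc[keep].copy(),
            batch=self.batch.loc[keep].copy(),
            duplicates=self.duplicates.loc[
                self.duplicates.index.intersection(keep)
            ].copy(),
        )


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-SNP metadata.

    ``dosages`` holds additive effect-allele dosages in [0, 2] (possibly
    fractional for imputed genotypes).  ``snp_info`` is indexed by snp_id with
    columns ``effect_allele``, ``rsq`` (imputation quality) and optional
    ``chrom``/``pos``.  ``stratum_maf`` holds the folded minor-allele
    frequency computed separately in men and women.
    """

    dosages: pd.DataFrame
    snp_info: pd.DataFrame
    stratum_maf: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if not self.snp_info.index.equals(self.dosages.columns):
            self.snp_info = self.snp_info.reindex(self.dosages.columns)
        rsq = self.snp_info["rsq"]
        if ((rsq <= 0) | (rsq > 1)).any():
            raise ValueError("imputation rsq must lie in (0, 1]")

    @property
    def snps(self) -> list[str]:
        return list(self.dosages.columns)


def stratum_allele_frequencies(
    dosages: pd.DataFrame, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Folded minor-allele frequency per SNP, separately by sex.

    The effect-allele frequency is mean(dosage)/2 within each stratum; the
    MAF folds it onto (0, 0.5].
    """
    validate_cohort(cohort)
    sex = cohort.set_index("sample_id")["sex"].reindex(dosages.index)
    out = {}
    for stratum in SEXES:
        sub = dosages.loc[(sex == stratum).to_numpy()]
        p = sub.mean(axis=0) / 2.0
        out[stratum] = np.minimum(p, 1 - p)
    return pd.DataFrame(out)
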