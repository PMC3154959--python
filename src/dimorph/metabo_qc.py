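"""Metabolite panel quality control.

The chain mirrors standard practice for targeted kit-based serum panels:

1. per-metabolite QC metrics (QC-replicate CV, %>LOD, duplicate correlation),
2. hard filters on those metrics,
3. QC-sample-based multiplicative batch adjustment,
4. sex-stratified robust multivariate outlier removal (standardize, project
   onto the unit sphere, robust Mahalanobis distances),
5. chained-regression imputation of missing values,
6. natural-log transform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.covariance import MinCovDet
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .datatypes import SEXES, MetaboliteMatrix, validate_cohort


@dataclass(frozen=True)
class QCThresholds:
    """Pass criteria: mean QC CV < cv_max, %>LOD >= lod_min_pct, duplicate
    Pearson r > dup_r_min."""

    cv_max: float = 0.25
    lod_min_pct: float = 90.0
    dup_r_min: float = 0.5


def qc_metrics(m: MetaboliteMatrix) -> pd.DataFrame:
    """Per-metabolite QC report.

    * ``mean_cv`` — for each QC sample within each batch, CV = SD/mean over
      its replicates; averaged over all QC samples.
    * ``pct_above_lod`` — percentage of study samples with an observed
      (non-censored, non-missing) concentration.
    * ``duplicate_r`` — Pearson correlation of first vs second measurement
      over the duplicate pairs.

    A metabolite whose metrics cannot be computed (all values missing, too
    few replicates or pairs) gets NaN metrics and fails overall.
    """
    mets = m.metabolites
    groups = m.qc.groupby(["batch", "qc_id"])
    if (groups.size() < 2).any():
        raise ValueError("need at least 2 QC replicates per QC sample and batch")
    if len(m.duplicates) < 3:
        raise ValueError("need at least 3 duplicate pairs for a defined correlation")

    cv = (groups[mets].std(ddof=1) / groups[mets].mean()).mean(axis=0)

    n = m.n_samples
    observed = m.values.notna() & ~m.below_lod
    pct_above = 100.0 * observed.sum(axis=0) / n if n else pd.Series(np.nan, index=mets)

    first = m.values.loc[m.duplicates.index, mets]
    dup_r = first.corrwith(m.duplicates[mets], axis=0)

    all_missing = m.values.isna().all(axis=0)
    cv[all_missing] = np.nan
    dup_r[all_missing] = np.nan

    thr = QCThresholds()
    report = pd.DataFrame(
        {
            "class": m.classes,
            "mean_cv": cv,
            "pct_above_lod": pct_above,
            "duplicate_r": dup_r,
        }
    )
    report["pass_cv"] = report["mean_cv"] < thr.cv_max
    report["pass_lod"] = report["pct_above_lod"] >= thr.lod_min_pct
    report["pass_dup"] = report["duplicate_r"] > thr.dup_r_min
    report["pass_overall"] = (
        report[["pass_cv", "pass_lod", "pass_dup"]].fillna(False).all(axis=1)
    )
    return report


def apply_qc_filters(
    report: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> list[str]:
    """Metabolites passing all three criteria, in report order."""
    ok = (
        (report["mean_cv"] < thresholds.cv_max)
        & (report["pct_above_lod"] >= thresholds.lod_min_pct)
        & (report["duplicate_r"] > thresholds.dup_r_min)
    )
    return list(report.index[ok.fillna(False)])


def qc_normalize_batches(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Divide each metabolite's concentrations by its batch QC mean relative
    to the grand QC mean, removing multiplicative batch effects.

    The grand QC mean is the unweighted mean of the batch QC means, so it is
    invariant under the adjustment.  QC replicate tables are adjusted with
    the same factors.
    """
    mets = m.metabolites
    sample_batches = pd.unique(m.batch)
    qc_batches = set(m.qc["batch"].unique())
    missing = [b for b in sample_batches if b not in qc_batches]
    if missing:
        raise ValueError(f"no QC samples for batch(es) {missing}")

    batch_means = m.qc.groupby("batch")[mets].mean()
    bad = batch_means.isna() | (batch_means <= 0)
    if bad.any().any():
        b = batch_means.index[bad.any(axis=1)][0]
        raise ValueError(f"zero or missing QC mean in batch {b}")
    grand = batch_means.mean(axis=0)
    factors = batch_means / grand  # batches x metabolites

    values = m.values / factors.loc[m.batch].set_axis(m.values.index)
    qc = m.qc.copy()
    qc[mets] = qc[mets] / factors.loc[qc["batch"]].to_numpy()
    duplicates = m.duplicates / factors.loc[
        m.batch.loc[m.duplicates.index]
    ].set_axis(m.duplicates.index)
    return replace(m, values=values, qc=qc, duplicates=duplicates, normalized=True)


def _robust_distances(X: np.ndarray, random_state: int) -> np.ndarray:
    """Standardize columns, project rows onto the unit sphere, and return
    robust Mahalanobis distances (minimum-covariance-determinant scatter)."""
    sd = X.std(axis=0, ddof=1)
    mean = X.mean(axis=0)
    Z = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    norms = np.linalg.norm(Z, axis=1)
    if np.all(norms == 0):  # all samples identical after standardization
        return np.zeros(len(Z))
    U = Z / np.where(norms > 0, norms, 1.0)[:, None]
    mcd = MinCovDet(random_state=random_state).fit(U)
    return np.sqrt(mcd.mahalanobis(U))


def detect_outliers(
    m: MetaboliteMatrix,
    cohort: pd.DataFrame,
    spread: str = "variance",
    random_state: int = 0,
) -> dict[str, list[str]]:
    """Sex-stratified robust multivariate outlier detection.

    Within each sex stratum the metabolite matrix is scaled to zero mean and
    unit SD, rows are projected onto the unit sphere, and Mahalanobis
    distances are computed from a robust (minimum covariance determinant)
    location/scatter estimate.  A sample is an outlier when its distance
    exceeds mean(d) + 3*Var(d) (``spread="variance"``, the default) or
    mean(d) + 3*SD(d) (``spread="sd"``).

    Returns ``{"male": [...], "female": [...]}``.  Complete cases only; a
    stratum with fewer samples than metabolites+1 raises.
    """
    if spread not in ("variance", "sd"):
        raise ValueError("spread must be 'variance' or 'sd'")
    validate_cohort(cohort)
    sex = cohort.set_index("sample_id")["sex"].reindex(m.values.index)
    out: dict[str, list[str]] = {}
    for stratum in SEXES:
        sub = m.values.loc[(sex == stratum).to_numpy()].dropna(axis=0, how="any")
        n, p = sub.shape
        if n < p + 1:
            raise ValueError(
                f"stratum {stratum!r} has {n} complete samples for {p} metabolites; "
                "need at least n_metabolites+1"
            )
        d = _robust_distances(sub.to_numpy(float), random_state)
        scale = d.var(ddof=1) if spread == "variance" else d.std(ddof=1)
        cutoff = d.mean() + 3.0 * scale
        out[stratum] = list(sub.index[d > cutoff])
    return out


def impute_missing(
    m: MetaboliteMatrix, method: str = "chained", seed: int = 0
) -> MetaboliteMatrix:
    """Fill missing values (including below-LOD censored entries).

    ``chained`` (default) is iterative per-column regression on the remaining
    columns, 10 sweeps, deterministic given ``seed`` — a deterministic
    analogue of chained-equations imputation.  ``median`` substitutes the
    column median.  Imputed concentrations are floored at half the smallest
    observed value of their column so the result stays positive.
    """
    if m.values.isna().all(axis=0).any():
        bad = m.values.columns[m.values.isna().all(axis=0)][0]
        raise ValueError(f"metabolite {bad!r} has no observed values")
    if not m.values.isna().any().any():
        return replace(m, imputed=True)
    if method == "chained":
        imp = IterativeImputer(max_iter=10, random_state=seed, sample_posterior=False)
        filled = imp.fit_transform(m.values.to_numpy(float))
    elif method == "median":
        med = m.values.median(axis=0).to_numpy()
        filled = m.values.to_numpy(float).copy()
        idx = np.where(np.isnan(filled))
        filled[idx] = med[idx[1]]
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    floor = 0.5 * np.nanmin(m.values.to_numpy(float), axis=0)
    was_nan = m.values.isna().to_numpy()
    filled = np.where(was_nan, np.maximum(filled, floor[None, :]), filled)
    values = pd.DataFrame(filled, index=m.values.index, columns=m.values.columns)
    return replace(m, values=values, imputed=True)


def log_transform(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Natural-log transform; requires strictly positive values and refuses a
    second application (state flag)."""
    if m.logged:
        raise ValueError("matrix is already log-transformed")
    bad = (m.values <= 0) & m.values.notna()
    if bad.any().any():
        col = m.values.columns[bad.any(axis=0)][0]
        row = m.values.index[bad[col]][0]
        raise ValueError(f"non-positive concentration at sample {row!r}, "
                         f"metabolite {col!r}")
    return replace(m, values=np.log(m.values), logged=True)
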