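"""Per-metabolite sex-effect estimation.

Each metabolite's natural-log concentration is regressed on a sex indicator
(male = 1, female = 0, so a positive beta means higher concentrations in men)
plus a configurable covariate set; the relative concentration difference
Delta, Bonferroni thresholds, a sign-consistent replication rule,
inverse-variance fixed-effect meta-analysis across cohorts, and two-component
PLS scores for visualizing the global male/female separation complete the
module.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .datatypes import MetaboliteMatrix, validate_cohort
from .sexdiff_gwas import inverse_variance_meta

#: Covariate sets, keyed by model id.  The batch indicator enters every model
#: unless ``include_batch=False``.
MODELS: dict[str, list[str]] = {
    "base": ["age", "bmi"],
    "whr": ["age", "whr"],
    "bmi_whr": ["age", "bmi", "whr"],
    "lipids": ["age", "bmi", "hdl", "ldl", "triglycerides"],
    "t2d": ["age", "bmi", "t2d"],
    "lifestyle": ["age", "bmi", "smoker", "high_alcohol"],
}


@dataclass
class SexEffectRecord:
    """OLS sex-effect estimate for one metabolite under one covariate model."""

    metabolite: str
    model: str
    beta_sex: float
    se: float
    p: float
    r2: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _design(cohort: pd.DataFrame, covariates: list[str], include_batch: bool
            ) -> pd.DataFrame:
    X = pd.DataFrame(index=cohort.index)
    X["sex_male"] = (cohort["sex"] == "male").astype(float)
    for c in covariates:
        X[c] = cohort[c].astype(float)
    if include_batch:
        dummies = pd.get_dummies(cohort["batch"], prefix="batch", drop_first=True)
        X = pd.concat([X, dummies.astype(float)], axis=1)
    return X


def fit_sex_effect(
    metabolite: str,
    cohort: pd.DataFrame,
    m: MetaboliteMatrix,
    covariates: str = "base",
    include_batch: bool = True,
) -> SexEffectRecord:
    """OLS of the logged metabolite on sex plus the covariate set.

    Complete cases only.  Returns the sex coefficient (male vs female), its
    standard error, the two-sided p-value from the t-distribution with
    residual degrees of freedom, the full-model R^2 and the n used.
    """
    if covariates not in MODELS:
        raise ValueError(f"unknown model {covariates!r}; choose from {list(MODELS)}")
    if not m.logged:
        raise ValueError("metabolite matrix must be log-transformed first")
    validate_cohort(cohort)

    y = m.values[metabolite]
    cohort_idx = cohort.set_index("sample_id")
    common = y.dropna().index.intersection(cohort_idx.index)
    sub = cohort_idx.loc[common]
    X = _design(sub.reset_index(), MODELS[covariates], include_batch)
    X.index = common
    keep = X.notna().all(axis=1)
    X, yv = X.loc[keep], y.loc[common][keep]

    if yv.nunique() <= 1:
        raise ValueError(f"metabolite {metabolite!r} is constant on complete cases")
    Xd = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(yv.to_numpy(), Xd).fit()
    return SexEffectRecord(
        metabolite=metabolite,
        model=covariates,
        beta_sex=float(fit.params["sex_male"]),
        se=float(fit.bse["sex_male"]),
        p=float(fit.pvalues["sex_male"]),
        r2=float(fit.rsquared),
        n=int(fit.nobs),
    )


def sex_effect_table(
    cohort: pd.DataFrame,
    m: MetaboliteMatrix,
    covariates: str = "base",
    include_batch: bool = True,
) -> pd.DataFrame:
    """Fit every metabolite; returns a frame indexed by metabolite with
    columns beta_sex, se, p, r2, n."""
    records = [
        fit_sex_effect(met, cohort, m, covariates, include_batch)
        for met in m.metabolites
    ]
    df = pd.DataFrame([r.to_dict() for r in records]).set_index("metabolite")
    return df.drop(columns="model")


def delta(mean_men, mean_women):
    """Relative sex difference in percent: 100*(mean_men - mean_women)/mean_men.

    Negative when women have the higher mean concentration.  Accepts scalars
    or aligned arrays/Series; ``mean_men`` must be positive.
    """
    mean_men = np.asarray(mean_men, dtype=float)
    mean_women = np.asarray(mean_women, dtype=float)
    if (mean_men <= 0).any():
        raise ValueError("mean concentration in men must be positive")
    out = 100.0 * (mean_men - mean_women) / mean_men
    return float(out) if out.ndim == 0 else out


def delta_table(cohort: pd.DataFrame, m: MetaboliteMatrix) -> pd.Series:
    """Delta (percent) per metabolite from raw concentration stratum means.

    Expects an *unlogged* matrix (raw concentrations)."""
    if m.logged:
        raise ValueError("delta is defined on raw concentrations, not logs")
    sex = cohort.set_index("sample_id")["sex"].reindex(m.values.index)
    men = m.values.loc[(sex == "male").to_numpy()].mean(axis=0)
    women = m.values.loc[(sex == "female").to_numpy()].mean(axis=0)
    return pd.Series(delta(men, women), index=m.values.columns, name="delta_pct")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def replicate_sex_effects(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Replication of discovery-significant sex effects.

    ``discovery`` and ``replication`` are frames indexed by metabolite with
    columns ``beta_sex`` and ``p``.  Metabolites significant in discovery at
    alpha/n_discovery are carried forward; a carried metabolite replicates
    iff its replication beta has the same sign and its replication p-value is
    below alpha/(number carried forward).  Metabolites absent from the
    replication cohort get a missing (undefined) flag, not False.
    """
    n_disc = len(discovery)
    disc_thr = bonferroni_threshold(alpha, n_disc)
    carried = discovery.index[discovery["p"] < disc_thr]
    if len(carried) == 0:
        return pd.DataFrame(
            columns=["replicated", "replication_threshold"], index=carried
        )
    rep_thr = bonferroni_threshold(alpha, len(carried))
    flags = []
    for met in carried:
        if met not in replication.index or pd.isna(replication.loc[met, "p"]):
            flags.append(pd.NA)
            continue
        same_sign = np.sign(replication.loc[met, "beta_sex"]) == np.sign(
            discovery.loc[met, "beta_sex"]
        )
        flags.append(bool(same_sign and replication.loc[met, "p"] < rep_thr))
    return pd.DataFrame(
        {"replicated": pd.array(flags, dtype="boolean"),
         "replication_threshold": rep_thr},
        index=carried,
    )


def meta_sex_effects(records: Sequence[SexEffectRecord]) -> SexEffectRecord:
    """Inverse-variance fixed-effect combination of one metabolite's
    sex-effect estimates across cohorts; combined p from the pooled z."""
    records = list(records)
    if not records:
        raise ValueError("need at least one cohort record")
    mets = {r.metabolite for r in records}
    if len(mets) > 1:
        raise ValueError(f"records mix metabolites: {sorted(mets)}")
    beta, se = inverse_variance_meta([(r.beta_sex, r.se) for r in records])
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return SexEffectRecord(
        metabolite=records[0].metabolite,
        model="meta(" + "+".join(r.model for r in records) + ")",
        beta_sex=beta,
        se=se,
        p=float(p),
        r2=float("nan"),
        n=sum(r.n for r in records),
    )


def pls_scores(
    X, y, n_components: int = 2, scale: bool = True
) -> np.ndarray:
    """Per-sample scores of the first ``n_components`` PLS1 components of X
    against the sex indicator y.

    X is standardized to zero mean / unit SD per metabolite (``scale=True``;
    pass False if already standardized).  Components follow the NIPALS
    solution with a fixed sign convention: the first nonzero entry of each
    weight vector is non-negative, so scores are reproducible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if len(y) != X.shape[0]:
        raise ValueError("X and y have different numbers of samples")
    if X.shape[0] <= n_components:
        raise ValueError("need more samples than components")
    if np.unique(y).size < 2:
        raise ValueError("y is constant: no discriminating direction exists")
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant metabolite column; drop it before PLS")
        X = (X - X.mean(axis=0)) / sd
    n_components = min(n_components, X.shape[1])
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y - y.mean())
    scores = pls.x_scores_.copy()
    weights = pls.x_weights_
    for k in range(n_components):
        w = weights[:, k]
        nz = np.flatnonzero(w)
        if nz.size and w[nz[0]] < 0:
            scores[:, k] = -scores[:, k]
    return scores
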