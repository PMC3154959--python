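"""Shared fixtures: small synthetic cohorts, panels and matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dimorph.datatypes import MetaboliteMatrix
from dimorph.synthdata import PanelSpec, block_correlation, generate_cohort


def make_cohort(n_male=60, n_female=60, seed=1, **overrides) -> pd.DataFrame:
    return generate_cohort(n_male, n_female, seed, overrides or None)


def make_panel(
    names,
    classes=None,
    log_mean=3.0,
    log_sd=0.25,
    beta_sex=0.0,
    beta_age=0.0,
    beta_bmi=0.0,
    lod=0.0,
    qc_cv=0.08,
    dup_log_sd=0.1,
    rho=0.0,
    block_size=3,
    n_batches=3,
    batch_shift_sd=0.0,
    shift_seed=0,
    **panel_kwargs,
) -> PanelSpec:
    """Build a small PanelSpec; scalar parameters broadcast over metabolites."""
    names = list(names)
    p = len(names)

    def col(v):
        return np.broadcast_to(np.asarray(v, dtype=object), (p,)).astype(float)

    classes = pd.Series(
        classes if classes is not None else ["aa"] * p, index=names
    )
    table = pd.DataFrame(
        {
            "class": classes,
            "log_mean": col(log_mean),
            "log_sd": col(log_sd),
            "beta_sex": col(beta_sex),
            "beta_age": col(beta_age),
            "beta_bmi": col(beta_bmi),
            "lod": col(lod),
            "qc_cv": col(qc_cv),
            "dup_log_sd": col(dup_log_sd),
        },
        index=pd.Index(names, name="metabolite"),
    )
    rng = np.random.default_rng(shift_seed)
    shifts = pd.DataFrame(
        rng.normal(0.0, batch_shift_sd, (n_batches, p)) if batch_shift_sd else
        np.zeros((n_batches, p)),
        index=range(n_batches),
        columns=names,
    )
    corr = (
        block_correlation(classes, rho=rho, block_size=block_size)
        if rho
        else pd.DataFrame(np.eye(p), index=names, columns=names)
    )
    return PanelSpec(table=table, batch_shifts=shifts, correlation=corr,
                     **panel_kwargs)


def make_matrix(values: pd.DataFrame, batch=None, qc=None, duplicates=None,
                lod=None, **flags) -> MetaboliteMatrix:
    """Wrap a plain values frame in a MetaboliteMatrix with minimal metadata."""
    mets = list(values.columns)
    if qc is None:
        qc = pd.DataFrame(columns=["batch", "qc_id", "replicate"] + mets)
    if duplicates is None:
        duplicates = pd.DataFrame(columns=mets)
    if batch is None:
        batch = pd.Series(0, index=values.index, name="batch")
    return MetaboliteMatrix(
        values=values,
        lod=pd.Series(0.0, index=mets) if lod is None else lod,
        classes=pd.Series("aa", index=mets),
        qc=qc,
        duplicates=duplicates,
        batch=batch,
        **flags,
    )


@pytest.fixture(scope="session")
def cohort():
    return make_cohort(150, 160, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
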