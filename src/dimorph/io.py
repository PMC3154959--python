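"""Delimited-text serialization for cohorts, metabolite panels and genotypes.

Everything is plain TSV (plus small JSON sidecars), so fixture sets are
human-readable and diffable.  A dataset directory contains::

    cohort.tsv                  one row per sample
    metabolites.tsv             samples x metabolites concentrations
    metabolite_info.tsv         metabolite, class, lod
    below_lod.tsv               0/1 censoring flags, same shape as values
    qc_samples.tsv              long table of QC replicate measurements
    duplicate_measurements.tsv  re-measured samples (subset) x metabolites
    metabolite_state.json       processing-state flags
    dosages.tsv                 samples x SNPs (optional)
    snp_info.tsv                SNP metadata sidecar (optional)
    manifest.json               scenario manifest with planted truth (optional)

Floats are written with Python's shortest round-trip repr, so write/read
cycles are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import GenotypeMatrix, MetaboliteMatrix, validate_cohort

_BOOL_COLS = ["t2d", "smoker", "high_alcohol"]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    validate_cohort(cohort)
    out = cohort.copy()
    for c in _BOOL_COLS:
        out[c] = out[c].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for c in _BOOL_COLS:
        cohort[c] = cohort[c].astype(bool)
    for c in ("age", "bmi", "whr", "hdl", "ldl", "triglycerides"):
        cohort[c] = cohort[c].astype(float)
    cohort["batch"] = cohort["batch"].astype(int)
    return validate_cohort(cohort)


def write_metabolites(m: MetaboliteMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m.values.rename_axis("sample_id").to_csv(outdir / "metabolites.tsv", sep="\t")
    info = pd.DataFrame(
        {"class": m.classes, "lod": m.lod, "batch_na": ""}
    ).drop(columns="batch_na")
    info.rename_axis("metabolite").to_csv(outdir / "metabolite_info.tsv", sep="\t")
    m.below_lod.astype(int).rename_axis("sample_id").to_csv(
        outdir / "below_lod.tsv", sep="\t"
    )
    m.qc.to_csv(outdir / "qc_samples.tsv", sep="\t", index=False)
    m.duplicates.rename_axis("sample_id").to_csv(
        outdir / "duplicate_measurements.tsv", sep="\t"
    )
    m.batch.rename("batch").rename_axis("sample_id").to_csv(
        outdir / "sample_batches.tsv", sep="\t"
    )
    state = {"normalized": m.normalized, "imputed": m.imputed, "logged": m.logged}
    (outdir / "metabolite_state.json").write_text(json.dumps(state, indent=1))


def read_metabolites(indir) -> MetaboliteMatrix:
    indir = Path(indir)
    values = pd.read_csv(
        indir / "metabolites.tsv", sep="\t", index_col="sample_id"
    )
    values.index = values.index.astype(str)
    info = pd.read_csv(indir / "metabolite_info.tsv", sep="\t", index_col="metabolite")
    below = pd.read_csv(indir / "below_lod.tsv", sep="\t", index_col="sample_id")
    below.index = below.index.astype(str)
    qc = pd.read_csv(indir / "qc_samples.tsv", sep="\t")
    dup = pd.read_csv(
        indir / "duplicate_measurements.tsv", sep="\t", index_col="sample_id"
    )
    dup.index = dup.index.astype(str)
    batch = pd.read_csv(indir / "sample_batches.tsv", sep="\t", index_col="sample_id")[
        "batch"
    ]
    batch.index = batch.index.astype(str)
    state = json.loads((indir / "metabolite_state.json").read_text())
    return MetaboliteMatrix(
        values=values,
        lod=info["lod"],
        classes=info["class"],
        qc=qc,
        duplicates=dup,
        batch=batch,
        below_lod=below.astype(bool),
        **state,
    )


def write_genotypes(g: GenotypeMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g.dosages.rename_axis("sample_id").to_csv(outdir / "dosages.tsv", sep="\t")
    info = g.snp_info.copy()
    if g.stratum_maf is not None:
        info["maf_male"] = g.stratum_maf["male"]
        info["maf_female"] = g.stratum_maf["female"]
    info.rename_axis("snp_id").to_csv(outdir / "snp_info.tsv", sep="\t")


def read_genotypes(indir) -> GenotypeMatrix:
    indir = Path(indir)
    dosages = pd.read_csv(indir / "dosages.tsv", sep="\t", index_col="sample_id")
    dosages.index = dosages.index.astype(str)
    info = pd.read_csv(indir / "snp_info.tsv", sep="\t", index_col="snp_id")
    maf = None
    if {"maf_male", "maf_female"} <= set(info.columns):
        maf = pd.DataFrame(
            {"male": info.pop("maf_male"), "female": info.pop("maf_female")}
        )
    return GenotypeMatrix(dosages=dosages, snp_info=info, stratum_maf=maf)


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
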