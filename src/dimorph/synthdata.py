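"""Synthetic cohorts, metabolite panels and genotypes.

The generator emulates the statistical structure of a population-based
targeted serum metabolomics study: log-normal metabolite concentrations with
additive sex/age/BMI effects on the log scale, within-class residual
correlation, multiplicative batch shifts, limit-of-detection censoring,
plate QC-sample replicates, duplicate re-measurements, and Hardy-Weinberg
SNPs whose per-allele effect on a log-concentration may differ between men
and women.  All draws are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .datatypes import (
    GenotypeMatrix,
    MetaboliteMatrix,
    stratum_allele_frequencies,
    validate_cohort,
)

# Centering constants for the age/BMI terms of the linear predictor, so that
# with all slopes zero the log-mean is exactly the configured baseline.
AGE_REF = 55.0
BMI_REF = 27.0


@dataclass
class CohortParams:
    """Demographic ranges for the simulated cohort (configuration, not constants)."""

    age_range: tuple[float, float] = (32.0, 81.0)
    bmi_mean: dict = field(default_factory=lambda: {"male": 27.8, "female": 27.0})
    bmi_sd: float = 4.2
    whr_mean: dict = field(default_factory=lambda: {"male": 0.93, "female": 0.81})
    whr_sd: float = 0.06
    hdl_mean: dict = field(default_factory=lambda: {"male": 51.0, "female": 63.0})
    hdl_sd: float = 13.0
    ldl_mean: float = 137.0
    ldl_sd: float = 35.0
    trig_log_mean: float = 4.7
    trig_log_sd: float = 0.5
    t2d_rate: float = 0.07
    smoker_rate: float = 0.19
    high_alcohol_rate: dict = field(
        default_factory=lambda: {"male": 0.26, "female": 0.12}
    )
    n_batches: int = 3


def generate_cohort(
    n_male: int, n_female: int, seed: int, param_overrides: dict | None = None
) -> pd.DataFrame:
    """Simulate a cohort table with ``n_male + n_female`` samples.

    Deterministic given ``seed``; samples are interleaved at random so batch
    and sex are independent by construction.
    """
    if n_male < 0 or n_female < 0:
        raise ValueError("sample counts must be non-negative")
    params = CohortParams(**(param_overrides or {}))
    rng = np.random.default_rng(seed)
    n = n_male + n_female
    sex = np.array(["male"] * n_male + ["female"] * n_female, dtype=object)
    rng.shuffle(sex)

    lo, hi = params.age_range
    age = np.round(rng.uniform(lo, hi, n), 1)
    bmi_mu = np.where(sex == "male", params.bmi_mean["male"], params.bmi_mean["female"])
    bmi = np.round(np.clip(rng.normal(bmi_mu, params.bmi_sd), 16, None), 2)
    whr_mu = np.where(sex == "male", params.whr_mean["male"], params.whr_mean["female"])
    whr = np.round(rng.normal(whr_mu, params.whr_sd), 3)
    hdl_mu = np.where(sex == "male", params.hdl_mean["male"], params.hdl_mean["female"])
    hdl = np.round(np.clip(rng.normal(hdl_mu, params.hdl_sd), 15, None), 1)
    ldl = np.round(np.clip(rng.normal(params.ldl_mean, params.ldl_sd, n), 30, None), 1)
    trig = np.round(np.exp(rng.normal(params.trig_log_mean, params.trig_log_sd, n)), 1)
    t2d = rng.random(n) < params.t2d_rate
    smoker = rng.random(n) < params.smoker_rate
    alc_rate = np.where(
        sex == "male",
        params.high_alcohol_rate["male"],
        params.high_alcohol_rate["female"],
    )
    high_alcohol = rng.random(n) < alc_rate
    batch = rng.integers(0, params.n_batches, n)

    cohort = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "whr": whr,
            "batch": batch,
            "hdl": hdl,
            "ldl": ldl,
            "triglycerides": trig,
            "t2d": t2d,
            "smoker": smoker,
            "high_alcohol": high_alcohol,
        }
    )
    return validate_cohort(cohort)


# ---------------------------------------------------------------------------
# Metabolite panel specification


@dataclass
class PanelSpec:
    """Generative parameters of a metabolite panel.

    ``table`` is indexed by metabolite name with columns ``class`` (compound
    class), ``log_mean``/``log_sd`` (baseline natural-log concentration),
    ``beta_sex`` (male-vs-female shift on the log scale, male coded 1),
    ``beta_age`` (per year), ``beta_bmi`` (per kg/m^2), ``lod``, ``qc_cv``
    (log-scale SD of QC replicate noise, approx. the CV), and ``dup_log_sd``
    (log-scale SD of duplicate re-measurement noise).  ``batch_shifts`` is a
    batches x metabolites frame of additive log-scale shifts.
    ``correlation`` is the residual (noise) correlation matrix.
    """

    table: pd.DataFrame
    batch_shifts: pd.DataFrame
    correlation: pd.DataFrame
    n_qc_samples: int = 3
    n_qc_replicates: int = 5
    n_duplicates: int = 40

    def __post_init__(self) -> None:
        if (self.table["log_sd"] <= 0).any():
            raise ValueError("log_sd must be positive")
        if (self.table["lod"] < 0).any():
            raise ValueError("LOD must be non-negative")

    @property
    def metabolites(self) -> list[str]:
        return list(self.table.index)


def block_correlation(
    classes: pd.Series, rho: float = 0.7, block_size: int = 3
) -> pd.DataFrame:
    """Exchangeable correlation within consecutive sub-blocks of each class.

    Small tight blocks (default triples with rho=0.7) give the panel a
    recoverable direct-correlation structure: the implied within-block
    partial correlations stay well above typical network cutoffs while
    between-block entries are exactly zero.
    """
    if not -1.0 / max(block_size - 1, 1) < rho < 1.0:
        raise ValueError("rho outside the positive-definite range for the block size")
    names = list(classes.index)
    corr = np.eye(len(names))
    start = 0
    blocks = []
    for _, group in classes.groupby(classes, sort=False):
        members = list(group.index)
        for i in range(0, len(members), block_size):
            blocks.append(members[i : i + block_size])
    name_pos = {n: i for i, n in enumerate(names)}
    for block in blocks:
        idx = [name_pos[n] for n in block]
        for a in idx:
            for b in idx:
                if a != b:
                    corr[a, b] = rho
    return pd.DataFrame(corr, index=names, columns=names)


_CLASS_PLAN = [
    # (class, n, sign of beta_sex: +1 higher in men / -1 higher in women)
    ("amino acid", 14, +1),
    ("acylcarnitine", 24, +1),
    ("PC aa", 38, -1),
    ("PC ae", 38, -1),
    ("lysoPC", 8, +1),
    ("sphingomyelin", 8, -1),
    ("hexose", 1, +1),
]

_CLASS_PREFIX = {
    "amino acid": "AA",
    "acylcarnitine": "C",
    "PC aa": "PC aa C",
    "PC ae": "PC ae C",
    "lysoPC": "lysoPC a C",
    "sphingomyelin": "SM C",
    "hexose": "H",
}

# A few named members with effect sizes on the scale reported for large
# population panels (log-scale male-vs-female shifts around +-0.1..0.25).
_NAMED = {
    "Gly": ("amino acid", -0.130),
    "Ser": ("amino acid", -0.130),
    "xLeu": ("amino acid", 0.206),
    "Val": ("amino acid", 0.142),
    "C18": ("acylcarnitine", 0.146),
    "H1": ("hexose", 0.065),
}


def default_panel(
    n_batches: int = 3,
    rho: float = 0.7,
    block_size: int = 3,
    spec_seed: int = 20110811,
    null_effects: bool = False,
) -> PanelSpec:
    """Default 131-metabolite panel: 7 compound classes, class-typical sex
    effects, tight residual-correlation triples, mild batch shifts.

    The parameter table is drawn once from ``spec_seed`` and is study
    configuration: the same panel is produced every time.
    """
    rng = np.random.default_rng(spec_seed)
    rows = []
    named_by_class: dict[str, list] = {}
    for name, (cls, beta) in _NAMED.items():
        named_by_class.setdefault(cls, []).append((name, beta))
    for cls, count, sign in _CLASS_PLAN:
        named = named_by_class.get(cls, [])
        for j in range(count):
            if j < len(named):
                name, beta_sex = named[j]
            else:
                prefix = _CLASS_PREFIX[cls]
                if cls in ("PC aa", "PC ae", "lysoPC", "sphingomyelin"):
                    name = f"{prefix}{28 + 2 * (j // 4)}:{j % 4}"
                elif cls == "acylcarnitine":
                    name = f"{prefix}{j}:{j % 2}"
                else:
                    name = f"{prefix}{j:02d}"
                beta_sex = sign * rng.uniform(0.03, 0.25)
            rows.append(
                {
                    "metabolite": name,
                    "class": cls,
                    "log_mean": rng.uniform(0.5, 5.0),
                    "log_sd": rng.uniform(0.18, 0.35),
                    "beta_sex": 0.0 if null_effects else beta_sex,
                    "beta_age": 0.0 if null_effects else rng.uniform(-0.002, 0.006),
                    "beta_bmi": 0.0 if null_effects else rng.uniform(-0.008, 0.015),
                    "qc_cv": 0.08,
                    "dup_log_sd": 0.10,
                }
            )
    table = pd.DataFrame(rows).set_index("metabolite")
    # LOD three residual SDs below the baseline mean: ~0.1% censoring.
    table["lod"] = np.exp(table["log_mean"] - 3.0 * table["log_sd"])
    shifts = pd.DataFrame(
        0.0 if null_effects else rng.normal(0.0, 0.06, (n_batches, len(table))),
        index=range(n_batches),
        columns=table.index,
    )
    corr = block_correlation(table["class"], rho=rho, block_size=block_size)
    return PanelSpec(table=table, batch_shifts=shifts, correlation=corr)


def qc_demo_panel(n_batches: int = 3, spec_seed: int = 20110811) -> PanelSpec:
    """A 163-metabolite panel engineered so exactly 131 pass the three QC
    criteria: 11 fail on QC-replicate CV, 11 on LOD coverage, 10 on duplicate
    correlation."""
    base = default_panel(n_batches=n_batches, spec_seed=spec_seed)
    rng = np.random.default_rng(spec_seed + 1)
    extra = []
    for i in range(32):
        row = {
            "class": "acylcarnitine",
            "log_mean": rng.uniform(0.5, 5.0),
            "log_sd": rng.uniform(0.18, 0.35),
            "beta_sex": 0.0,
            "beta_age": 0.0,
            "beta_bmi": 0.0,
            "qc_cv": 0.08,
            "dup_log_sd": 0.10,
        }
        if i < 11:  # noisy QC replicates -> CV >> 25%
            name = f"FAILCV{i:02d}"
            row["qc_cv"] = 0.60
            row["lod"] = np.exp(row["log_mean"] - 3 * row["log_sd"])
        elif i < 22:  # LOD near the median -> ~50% of samples above LOD
            name = f"FAILLOD{i:02d}"
            row["lod"] = np.exp(row["log_mean"])
        else:  # duplicate re-measurements dominated by noise -> r << 0.5
            name = f"FAILDUP{i:02d}"
            row["dup_log_sd"] = 2.0
            row["lod"] = np.exp(row["log_mean"] - 3 * row["log_sd"])
        extra.append(pd.Series(row, name=name))
    table = pd.concat([base.table, pd.DataFrame(extra)])
    shifts = base.batch_shifts.reindex(columns=table.index, fill_value=0.0)
    corr = pd.DataFrame(
        np.eye(len(table)), index=table.index, columns=table.index
    )
    corr.loc[base.table.index, base.table.index] = base.correlation
    return PanelSpec(table=table, batch_shifts=shifts, correlation=corr)


def generate_metabolites(
    cohort: pd.DataFrame,
    panel: PanelSpec,
    seed: int,
    genetic_effects: pd.DataFrame | None = None,
) -> MetaboliteMatrix:
    """Simulate concentrations for ``cohort`` under ``panel``.

    log concentration = log_mean + beta_sex*male + beta_age*(age-55)
    + beta_bmi*(BMI-27) + batch shift [+ genetic effects] + correlated noise;
    entries below the LOD are reported missing with a below-LOD flag.
    """
    validate_cohort(cohort)
    rng = np.random.default_rng(seed)
    tbl = panel.table
    mets = panel.metabolites
    n, p = len(cohort), len(mets)

    corr = panel.correlation.loc[mets, mets].to_numpy()
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError("panel correlation matrix is not positive definite") from err

    male = (cohort["sex"] == "male").to_numpy(float)
    mu = (
        tbl["log_mean"].to_numpy()[None, :]
        + np.outer(male, tbl["beta_sex"].to_numpy())
        + np.outer(cohort["age"].to_numpy() - AGE_REF, tbl["beta_age"].to_numpy())
        + np.outer(cohort["bmi"].to_numpy() - BMI_REF, tbl["beta_bmi"].to_numpy())
        + panel.batch_shifts.loc[cohort["batch"], mets].to_numpy()
    )
    if genetic_effects is not None:
        ge = genetic_effects.reindex(
            index=cohort["sample_id"], columns=mets, fill_value=0.0
        )
        mu = mu + ge.to_numpy()
    noise = rng.standard_normal((n, p)) @ chol.T * tbl["log_sd"].to_numpy()[None, :]
    conc = np.exp(mu + noise)

    lod = tbl["lod"].to_numpy()
    below = conc < lod[None, :]
    values = pd.DataFrame(
        np.where(below, np.nan, conc), index=cohort["sample_id"], columns=mets
    )
    below_lod = pd.DataFrame(below, index=cohort["sample_id"], columns=mets)

    # Plate QC samples: per batch, n_qc_samples pooled-plasma levels, each
    # measured n_qc_replicates times with multiplicative log-normal noise.
    qc_offsets = np.linspace(-0.2, 0.2, panel.n_qc_samples)
    qc_rows = []
    for b in panel.batch_shifts.index:
        shift = panel.batch_shifts.loc[b, mets].to_numpy()
        for q, off in enumerate(qc_offsets):
            level = np.exp(tbl["log_mean"].to_numpy() + off + shift)
            for r in range(panel.n_qc_replicates):
                eps = rng.normal(0.0, tbl["qc_cv"].to_numpy())
                qc_rows.append(
                    dict(
                        zip(mets, level * np.exp(eps)),
                        batch=b,
                        qc_id=q,
                        replicate=r,
                    )
                )
    qc = pd.DataFrame(qc_rows)[["batch", "qc_id", "replicate"] + mets]

    # Duplicate re-measurements of a random subset of samples.
    n_dup = min(panel.n_duplicates, n)
    dup_ids = rng.choice(cohort["sample_id"].to_numpy(), size=n_dup, replace=False)
    dup_idx = cohort.set_index("sample_id").index.get_indexer(dup_ids)
    dup_noise = rng.normal(0.0, tbl["dup_log_sd"].to_numpy(), (n_dup, p))
    dup_conc = conc[dup_idx] * np.exp(dup_noise)
    duplicates = pd.DataFrame(dup_conc, index=pd.Index(dup_ids, name="sample_id"),
                              columns=mets)

    batch = pd.Series(
        cohort["batch"].to_numpy(), index=cohort["sample_id"], name="batch"
    )
    return MetaboliteMatrix(
        values=values,
        lod=tbl["lod"].copy(),
        classes=tbl["class"].copy(),
        qc=qc,
        duplicates=duplicates,
        batch=batch,
        below_lod=below_lod,
    )


# ---------------------------------------------------------------------------
# Genotypes


@dataclass
class SnpSpec:
    """A simulated SNP with (possibly) sex-specific per-allele effects on the
    natural-log concentration of one target metabolite."""

    snp_id: str
    maf: float
    target: str
    beta_men: float = 0.0
    beta_women: float = 0.0
    effect_allele: str = "A"
    rsq: float = 1.0
    chrom: int | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf must lie in (0, 0.5]")
        if not 0.0 < self.rsq <= 1.0:
            raise ValueError(f"{self.snp_id}: rsq must lie in (0, 1]")


def generate_genotypes(
    cohort: pd.DataFrame, snps: list[SnpSpec], seed: int
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate dosages and the genetic contribution to the log concentrations.

    Genotypes are Hardy-Weinberg draws (Binomial(2, maf) effect-allele
    counts).  Imputed dosages shrink the true genotype toward its expectation
    so that the empirical dosage-variance ratio matches the specified rsq:
    dosage = 2*maf + sqrt(rsq) * (genotype - 2*maf); rsq=1 reproduces the hard
    genotype.  The per-allele effect acts through the *true* genotype, with
    the sex-specific beta of the sample's stratum.

    Returns the GenotypeMatrix and a samples x metabolites frame of additive
    log-scale effects to pass to :func:`generate_metabolites`.  The effect
    columns are centered within each sex stratum, so sex-specific allele
    effects change within-stratum variation only and the panel's configured
    ``beta_sex`` remains the marginal male-female difference; per-allele
    slopes within a stratum are unaffected by the centering.
    """
    validate_cohort(cohort)
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    male = (cohort["sex"] == "male").to_numpy()
    ids = pd.Index(cohort["sample_id"], name="sample_id")

    dosages = {}
    targets = list(dict.fromkeys(s.target for s in snps))
    effects = pd.DataFrame(0.0, index=ids, columns=targets)
    info_rows = []
    for spec in snps:
        g = rng.binomial(2, spec.maf, n).astype(float)
        dosage = 2 * spec.maf + np.sqrt(spec.rsq) * (g - 2 * spec.maf)
        dosages[spec.snp_id] = dosage
        beta = np.where(male, spec.beta_men, spec.beta_women)
        effects[spec.target] += beta * g
        info_rows.append(
            {
                "snp_id": spec.snp_id,
                "effect_allele": spec.effect_allele,
                "rsq": spec.rsq,
                "chrom": spec.chrom,
                "pos": spec.pos,
                "target": spec.target,
            }
        )
    for stratum_mask in (male, ~male):
        if stratum_mask.any():
            effects.loc[stratum_mask] -= effects.loc[stratum_mask].mean()
    dosage_df = pd.DataFrame(dosages, index=ids)
    info = pd.DataFrame(info_rows).set_index("snp_id")
    maf = stratum_allele_frequencies(dosage_df, cohort) if snps else None
    return GenotypeMatrix(dosages=dosage_df, snp_info=info, stratum_maf=maf), effects


# ---------------------------------------------------------------------------
# Scenarios and fixture sets

#: SNPs emulating a locus with a strong female-specific effect on glycine
#: (effect sizes on the scale reported for CPS1-like loci) plus a null SNP.
GLYCINE_LOCUS_SNPS = [
    SnpSpec("snp_top", maf=0.31, target="Gly", beta_men=-0.067, beta_women=-0.206,
            effect_allele="T", rsq=0.98, chrom=2, pos=211421),
    SnpSpec("snp_coding", maf=0.32, target="Gly", beta_men=-0.078, beta_women=-0.22,
            effect_allele="C", rsq=0.97, chrom=2, pos=211540),
    SnpSpec("snp_null", maf=0.25, target="Gly", beta_men=0.0, beta_women=0.0,
            effect_allele="G", rsq=0.95, chrom=7, pos=5023),
]


def _scenario(name: str, seed: int):
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    if name == "default":
        cohort = generate_cohort(300, 320, child[0])
        panel = default_panel()
        geno, eff = generate_genotypes(cohort, GLYCINE_LOCUS_SNPS, child[1])
        m = generate_metabolites(cohort, panel, child[2], genetic_effects=eff)
        snps = GLYCINE_LOCUS_SNPS
    elif name == "null":
        cohort = generate_cohort(300, 320, child[0])
        panel = default_panel(null_effects=True)
        geno, eff, snps = None, None, []
        m = generate_metabolites(cohort, panel, child[2])
    elif name == "qc163":
        cohort = generate_cohort(300, 320, child[0])
        panel = qc_demo_panel()
        geno, snps = None, []
        m = generate_metabolites(cohort, panel, child[2])
    elif name == "gwas":
        cohort = generate_cohort(912, 897, child[0])
        panel = default_panel()
        geno, eff = generate_genotypes(cohort, GLYCINE_LOCUS_SNPS, child[1])
        m = generate_metabolites(cohort, panel, child[2], genetic_effects=eff)
        snps = GLYCINE_LOCUS_SNPS
    else:
        raise ValueError(f"unknown scenario {name!r}")
    return cohort, panel, m, geno, snps


SCENARIOS = ("default", "null", "qc163", "gwas")


def write_fixture_set(outdir, scenario_name: str = "default", seed: int = 0) -> dict:
    """Write a complete scenario to ``outdir`` and return its manifest.

    The manifest records every file with its row count plus the planted truth
    (per-metabolite sex betas, per-SNP sex-specific betas), so downstream
    estimates can be scored against what was simulated.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, panel, m, geno, snps = _scenario(scenario_name, seed)

    io.write_cohort(cohort, outdir / "cohort.tsv")
    io.write_metabolites(m, outdir)
    files = {
        "cohort.tsv": len(cohort),
        "metabolites.tsv": len(m.values),
        "metabolite_info.tsv": len(m.lod),
        "below_lod.tsv": len(m.below_lod),
        "qc_samples.tsv": len(m.qc),
        "duplicate_measurements.tsv": len(m.duplicates),
        "sample_batches.tsv": len(m.batch),
    }
    if geno is not None:
        io.write_genotypes(geno, outdir)
        files["dosages.tsv"] = len(geno.dosages)
        files["snp_info.tsv"] = len(geno.snp_info)
    manifest = {
        "scenario": scenario_name,
        "seed": seed,
        "files": files,
        "planted": {
            "beta_sex": panel.table["beta_sex"].to_dict(),
            "snps": [asdict(s) for s in snps],
        },
    }
    io.write_manifest(manifest, outdir / "manifest.json")
    return manifest
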