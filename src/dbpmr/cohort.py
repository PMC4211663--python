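"""Synthetic cohort generator for the DBP Mendelian-randomization design.

The generator draws participants from the structural model

    DBP   = mu0 + beta_g * G + covariate effects + lambda_d * U + eps
    trait = baseline + theta * (DBP - E[DBP]) / 50 + lambda_t * U + noise
    P(disease) = invlogit( logit(prev) + theta * (DBP - E[DBP]) / 50 + lambda_t * U )

where ``G`` is the per-participant count of the DBP-lowering effect allele
(drawn under Hardy-Weinberg equilibrium) and ``U`` is a single latent
standard-normal confounder shared by the exposure and every outcome.  ``U``
is deliberately *not* emitted in the cohort table: it is what makes
observational and causal effects diverge, and what the instrumental-variable
estimators must see through.  Causal effects ``theta`` are parameterised per
50 mg/l of DBP (one population SD), matching how results are reported.

The ``"camos"`` preset calibrates every parameter to the published cohort
marginals (allele frequency 0.288, DBP 369.6 +- 50.1 mg/l, trait means/SDs,
disease prevalences) and chooses confounder loadings so that the
observational and IV effect columns of the published results table are the
large-sample expectations of the corresponding analyses.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitParams",
    "TrueParams",
    "COHORT_COLUMNS",
    "TRAIT_COLUMNS",
    "DISEASE_COLUMNS",
    "camos_params",
    "get_preset",
    "PRESETS",
    "generate_genotypes",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "dbp_variance_components",
    "dbp_mean",
]

#: Continuous trait columns, in canonical order. PTH and fasting insulin are
#: generated on the natural-log scale (their analysis scale) and stored native.
TRAIT_COLUMNS = [
    "t25ohd",      # total 25-hydroxy-vitamin D, nmol/l
    "free25ohd",   # calculated free 25OHD, pmol/l
    "calcium",     # serum calcium, mmol/l
    "pth",         # parathyroid hormone, ng/l
    "glucose",     # fasting glucose, mmol/l
    "insulin",     # fasting insulin, pmol/l
    "bmi",         # body-mass index, kg/m^2
    "bmd",         # femoral-neck bone mineral density, g/cm^2
]

#: Binary disease flags (self-reported, prevalent disease).
DISEASE_COLUMNS = ["hypertension", "diabetes", "mi", "stroke_tia", "osteoporosis"]

#: Full cohort table header, fixed and documented.
COHORT_COLUMNS = (
    ["id", "genotype", "age", "sex", "ethnicity", "season", "dbp"]
    + TRAIT_COLUMNS
    + DISEASE_COLUMNS
)

#: Traits whose generative (and analysis) scale is the natural log.
LOG_SCALE_TRAITS = {"pth", "insulin"}


@dataclass
class TraitParams:
    """Generative parameters for one outcome.

    theta
        Causal effect per 50 mg/l DBP, in trait units on the analysis scale
        (log units for log-scale traits, log-odds for diseases).
    lambda_u
        Loading of the latent confounder U (trait units per SD of U).
    baseline
        Trait mean on the analysis scale, or baseline disease prevalence.
    resid_sd
        Residual SD on the analysis scale (continuous traits only).
    """

    theta: float
    lambda_u: float
    baseline: float
    resid_sd: float = 0.0
    log_scale: bool = False
    binary: bool = False


@dataclass
class TrueParams:
    """Full generative parameter set, retained for parameter-recovery tests."""

    maf: float
    beta_g_dbp: float           # mg/l per effect-allele copy
    dbp_intercept: float        # mg/l
    beta_female: float          # mg/l
    beta_age: float             # mg/l per year
    beta_non_european: float    # mg/l
    lambda_u_dbp: float         # mg/l per SD of U
    dbp_resid_sd: float         # mg/l
    traits: dict[str, TraitParams] = field(default_factory=dict)
    prop_female: float = 0.695
    age_mean: float = 65.7
    age_sd: float = 15.4
    age_min: float = 16.0
    age_max: float = 100.0
    prop_non_european: float = 0.054
    prop_cold_season: float = 0.552
    genotype_missing_rate: float = 0.0
    scale: float = 50.0         # mg/l per exposure SD unit of theta

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"maf must lie in [0, 1], got {self.maf}")
        for name in ("prop_female", "prop_non_european", "prop_cold_season"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("dbp_resid_sd", "age_sd", "scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.genotype_missing_rate < 1.0):
            raise ValueError("genotype_missing_rate must lie in [0, 1)")
        numeric = [
            self.maf, self.beta_g_dbp, self.dbp_intercept, self.beta_female,
            self.beta_age, self.beta_non_european, self.lambda_u_dbp,
            self.dbp_resid_sd, self.age_mean, self.age_sd,
        ]
        for t in self.traits.values():
            numeric += [t.theta, t.lambda_u, t.baseline, t.resid_sd]
            if t.binary and not (0.0 < t.baseline < 1.0):
                raise ValueError("disease baseline prevalence must lie in (0, 1)")
            if not t.binary and t.resid_sd < 0:
                raise ValueError("trait resid_sd must be non-negative")
        if not np.all(np.isfinite(numeric)):
            raise ValueError("TrueParams contains non-finite values")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrueParams":
        d = dict(d)
        d["traits"] = {k: TraitParams(**v) for k, v in d.get("traits", {}).items()}
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrueParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# analytic moments of the generative model
# ---------------------------------------------------------------------------

def _age_moments(p: TrueParams) -> tuple[float, float]:
    """Mean and variance of the truncated-normal age distribution."""
    a = (p.age_min - p.age_mean) / p.age_sd
    b = (p.age_max - p.age_mean) / p.age_sd
    m, v = stats.truncnorm.stats(a, b, loc=p.age_mean, scale=p.age_sd, moments="mv")
    return float(m), float(v)


def dbp_variance_components(p: TrueParams) -> dict[str, float]:
    """Analytic decomposition of the marginal DBP variance (mg^2/l^2)."""
    q = p.maf
    _, age_var = _age_moments(p)
    return {
        "genotype": p.beta_g_dbp**2 * 2.0 * q * (1.0 - q),
        "sex": p.beta_female**2 * p.prop_female * (1.0 - p.prop_female),
        "age": p.beta_age**2 * age_var,
        "ethnicity": p.beta_non_european**2
        * p.prop_non_european * (1.0 - p.prop_non_european),
        "confounder": p.lambda_u_dbp**2,
        "residual": p.dbp_resid_sd**2,
    }


def dbp_mean(p: TrueParams) -> float:
    """Analytic marginal mean of DBP (mg/l)."""
    age_mean, _ = _age_moments(p)
    return (
        p.dbp_intercept
        + p.beta_g_dbp * 2.0 * p.maf
        + p.beta_female * p.prop_female
        + p.beta_age * age_mean
        + p.beta_non_european * p.prop_non_european
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# Published cohort marginals: (mean, SD) on the native scale.
_TRAIT_MARGINALS = {
    "t25ohd": (68.9, 24.7),
    "free25ohd": (14.4, 5.1),
    "calcium": (2.38, 0.11),
    "pth": (62.4, 30.6),
    "glucose": (5.51, 1.11),
    "insulin": (65.4, 44.6),
    "bmi": (27.5, 5.4),
    "bmd": (0.741, 0.131),
}

# Published effect columns per 50 mg/l DBP on the analysis scale:
# (observational estimate, IV estimate). For traits these are slopes; the
# IV column is taken as the true causal effect theta and the confounder
# loading is solved so the observational column is the large-sample
# age/sex-adjusted regression slope.
_TRAIT_EFFECTS = {
    "t25ohd": (4.99, 8.17),
    "free25ohd": (-0.71, -0.11),
    "calcium": (0.01, 0.01),
    "pth": (-0.01, 0.02),
    "glucose": (-0.001, -3.6e-4),
    "insulin": (-0.02, 0.06),
    "bmi": (-0.53, 0.0),    # observationally negative, causally null
    "bmd": (0.002, 0.0),    # causally null
}

# Diseases: (observational OR, IV OR, adult prevalence) per 50 mg/l DBP.
_DISEASE_EFFECTS = {
    "hypertension": (0.91, 0.82, 0.432),
    "diabetes": (0.79, 1.00, 0.095),
    "mi": (0.90, 0.80, 0.090),
    "stroke_tia": (0.83, 0.51, 0.076),
    "osteoporosis": (0.96, 1.32, 0.224),
}

_DBP_MEAN, _DBP_SD = 369.6, 50.1


def _lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given native mean and SD."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def camos_params(
    confounding: bool = True,
    null_effects: bool = False,
    lambda_u_dbp: float = 30.0,
) -> TrueParams:
    """Build the cohort-calibrated parameter preset.

    Parameters
    ----------
    confounding
        If False, every confounder loading is zeroed (observational and IV
        estimands coincide); residual SDs are recomputed so the marginal
        means and SDs are preserved.
    null_effects
        If True, every causal effect theta is set to zero (the confounding
        structure, if enabled, is retained), for null-calibration studies.
    lambda_u_dbp
        Confounder loading on DBP, mg/l per SD of U.  The split of the
        non-genetic, non-covariate DBP variance between U and noise is not
        identified by the published marginals; 30 mg/l leaves a residual SD
        of ~32 mg/l and reproduces the published endogeneity-test behaviour.
    """
    lam_d = lambda_u_dbp if confounding else 0.0
    p = TrueParams(
        maf=0.288,
        beta_g_dbp=-27.6,
        dbp_intercept=0.0,          # placeholder, solved below
        beta_female=29.2,
        beta_age=-0.6,
        beta_non_european=-16.9,
        lambda_u_dbp=lam_d,
        dbp_resid_sd=1.0,           # placeholder, solved below
        traits={},
    )
    comp = dbp_variance_components(p)
    fixed_var = comp["genotype"] + comp["sex"] + comp["age"] + comp["ethnicity"]
    resid2 = _DBP_SD**2 - fixed_var - lam_d**2
    if resid2 <= 0:
        raise ValueError("lambda_u_dbp too large for the target DBP variance")
    p.dbp_resid_sd = math.sqrt(resid2)
    p.dbp_intercept = _DBP_MEAN - (dbp_mean(p) - p.dbp_intercept)

    v_total = _DBP_SD**2
    # Observational analyses adjust for age and sex, so the relevant DBP
    # variance for the confounding bias is the residual given age and sex.
    comp = dbp_variance_components(p)
    v_adj = v_total - comp["age"] - comp["sex"]

    def solve_loading(obs: float, theta: float) -> float:
        if not confounding:
            return 0.0
        return (obs - theta) * v_adj / (p.scale * lam_d)

    for name, (obs, iv) in _TRAIT_EFFECTS.items():
        mean, sd = _TRAIT_MARGINALS[name]
        log_scale = name in LOG_SCALE_TRAITS
        if log_scale:
            baseline, sd_a = _lognormal_moments(mean, sd)
        else:
            baseline, sd_a = mean, sd
        theta = 0.0 if null_effects else iv
        lam = solve_loading(obs, iv)
        s = theta / p.scale
        explained = s * s * v_total + lam * lam + 2.0 * s * lam * lam_d
        resid2 = sd_a**2 - explained
        if resid2 <= 0:
            raise ValueError(f"trait {name}: variance budget exhausted")
        p.traits[name] = TraitParams(
            theta=theta, lambda_u=lam, baseline=baseline,
            resid_sd=math.sqrt(resid2), log_scale=log_scale,
        )

    for name, (obs_or, iv_or, prev) in _DISEASE_EFFECTS.items():
        theta = 0.0 if null_effects else math.log(iv_or)
        lam = solve_loading(math.log(obs_or), math.log(iv_or))
        p.traits[name] = TraitParams(
            theta=theta, lambda_u=lam, baseline=prev, binary=True,
        )
    p.validate()
    return p


PRESETS = {
    "camos": lambda: camos_params(),
    "camos_noconf": lambda: camos_params(confounding=False),
    "null_all": lambda: camos_params(null_effects=True),
}


def get_preset(name: str) -> TrueParams:
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return factory()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_genotypes(n: int, maf: float, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` effect-allele counts under Hardy-Weinberg equilibrium.

    Each genotype is the sum of two independent Bernoulli(maf) allele draws.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0.0 <= maf <= 1.0):
        raise ValueError(f"maf must lie in [0, 1], got {maf}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.binomial(1, maf, size=(n, 2)).sum(axis=1)


def generate_cohort(
    params: TrueParams, n: int, seed: int | np.random.Generator
) -> tuple[pd.DataFrame, TrueParams]:
    """Simulate a cohort table of ``n`` participants.

    Returns the table together with the generative parameters used, so that
    downstream analyses can be checked by parameter recovery.
    """
    params.validate()
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = params

    genotype = generate_genotypes(n, p.maf, rng).astype(float)
    a = (p.age_min - p.age_mean) / p.age_sd
    b = (p.age_max - p.age_mean) / p.age_sd
    age = stats.truncnorm.rvs(a, b, loc=p.age_mean, scale=p.age_sd,
                              size=n, random_state=rng)
    female = rng.random(n) < p.prop_female
    non_european = rng.random(n) < p.prop_non_european
    cold = rng.random(n) < p.prop_cold_season
    u = rng.standard_normal(n)

    dbp = (
        p.dbp_intercept
        + p.beta_g_dbp * genotype
        + p.beta_female * female
        + p.beta_age * age
        + p.beta_non_european * non_european
        + p.lambda_u_dbp * u
        + rng.normal(0.0, p.dbp_resid_sd, n)
    )
    dbp_centred = (dbp - dbp_mean(p)) / p.scale

    data = {
        "id": np.arange(1, n + 1),
        "genotype": genotype,
        "age": age,
        "sex": np.where(female, "female", "male"),
        "ethnicity": np.where(non_european, "non_european", "european"),
        "season": np.where(cold, "cold", "warm"),
        "dbp": dbp,
    }
    for name, t in p.traits.items():
        lin = t.theta * dbp_centred + t.lambda_u * u
        if t.binary:
            eta = math.log(t.baseline / (1.0 - t.baseline)) + lin
            prob = 1.0 / (1.0 + np.exp(-eta))
            data[name] = (rng.random(n) < prob).astype(int)
        else:
            y = t.baseline + lin + rng.normal(0.0, t.resid_sd, n)
            data[name] = np.exp(y) if t.log_scale else y

    if p.genotype_missing_rate > 0:
        miss = rng.random(n) < p.genotype_missing_rate
        data["genotype"] = np.where(miss, np.nan, data["genotype"])

    cohort = pd.DataFrame(data)
    for col in COHORT_COLUMNS:
        if col not in cohort.columns:
            cohort[col] = np.nan
    return cohort[COHORT_COLUMNS], p


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

_MANDATORY_COLUMNS = ["id", "genotype", "age", "sex", "dbp"]


def write_cohort(cohort: pd.DataFrame, path: str | Path,
                 metadata: dict | None = None) -> None:
    """Write a cohort table as TSV, with optional '#' metadata header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        cohort.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort TSV, validating the header and genotype values."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                     float_precision="round_trip")
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks mandatory columns: {missing}")
    geno = df["genotype"]
    bad = geno.notna() & ~geno.isin([0, 1, 2])
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(
            f"invalid genotype value {geno[bad].iloc[0]!r} in column 'genotype', "
            f"row {row} of {path}: must be 0, 1, 2 or NA"
        )
    if len(df) and (df["dbp"].dropna() <= 0).any():
        raise ValueError(f"non-positive DBP value in {path}")
    return df
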