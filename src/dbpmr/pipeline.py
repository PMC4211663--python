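"""End-to-end analysis pipeline: preprocessing, observational and IV
regressions, multiple-testing control, free-25OHD computation, subgroups.

The pipeline reproduces the published analysis layout: a first-stage table
(genotype -> DBP), then per outcome an age/sex-adjusted observational
regression and an instrumental-variable analysis, both expressed per 50
mg/l (one SD) of DBP, with Bonferroni control across the configured number
of comparisons.  Continuous outcomes use two-stage least squares plus the
Durbin-Wu-Hausman endogeneity test; binary (disease) outcomes use the
control-function logistic estimator and are restricted to adults.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import (
    ControlFunctionLogisticIV,
    SeparationError,
    TwoStageLeastSquares,
    WeakInstrumentWarning,
    fit_linear,
    fit_logistic,
)

__all__ = [
    "OutcomeSpec",
    "AnalysisConfig",
    "default_config",
    "preprocess",
    "observational_analysis",
    "iv_analysis",
    "apply_bonferroni",
    "free_25ohd",
    "subgroup_analysis",
    "first_stage_table",
    "run_analysis",
    "render_text_table",
]


@dataclass
class OutcomeSpec:
    name: str
    kind: str = "continuous"          # 'continuous' | 'binary'
    transform: str = "none"           # 'none' | 'log'
    adult_only: bool = False

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if self.transform not in ("none", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class AnalysisConfig:
    """Tunable analysis settings (defaults follow the published protocol)."""

    outcomes: list[OutcomeSpec] = field(default_factory=lambda: _default_outcomes())
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    dbp_ceiling: float = 600.0        # mg/l; extreme-outlier exclusion for DBP
    outlier_sd: float = 3.5           # generic per-trait outlier rule
    scale: float = 50.0               # mg/l per reported SD unit
    alpha: float = 0.05
    n_comparisons: int = 12           # Bonferroni family size
    subgroup_threshold: float = 50.0  # nmol/l, vitamin-D-deficiency cutoff
    adult_age: float = 25.0           # diseases analysed at age >= this
    # free-hormone-calculation constants (exposed because they are tunable
    # literature values, not measured in the cohort)
    k_dbp: float = 7e8                # DBP binding affinity for 25OHD, 1/M
    k_alb: float = 6e5                # albumin binding affinity, 1/M
    mw_dbp: float = 58_000.0          # g/mol
    mw_alb: float = 66_400.0          # g/mol

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_comparisons < 1:
            raise ValueError("n_comparisons must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "outcomes" in d:
            d["outcomes"] = [
                o if isinstance(o, OutcomeSpec) else OutcomeSpec(**o)
                for o in d["outcomes"]
            ]
        return cls(**d)


def _default_outcomes() -> list[OutcomeSpec]:
    return [
        OutcomeSpec("t25ohd"),
        OutcomeSpec("free25ohd"),
        OutcomeSpec("calcium"),
        OutcomeSpec("pth", transform="log"),
        OutcomeSpec("glucose"),
        OutcomeSpec("insulin", transform="log"),
        OutcomeSpec("bmi"),
        OutcomeSpec("bmd"),
        OutcomeSpec("hypertension", kind="binary", adult_only=True),
        OutcomeSpec("diabetes", kind="binary", adult_only=True),
        OutcomeSpec("mi", kind="binary", adult_only=True),
        OutcomeSpec("stroke_tia", kind="binary", adult_only=True),
        OutcomeSpec("osteoporosis", kind="binary", adult_only=True),
    ]


def default_config() -> AnalysisConfig:
    return AnalysisConfig()


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(cohort: pd.DataFrame, config: AnalysisConfig | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply outlier exclusion and transforms; return (cohort, exclusion log).

    Order: rows with DBP above the ceiling are dropped first; then, per
    continuous outcome, the log transform (if configured) is applied with
    non-positive values set missing; finally values beyond
    ``outlier_sd`` SDs from the mean (on the analysis scale) are set
    missing.  The exclusion log records a row per rule with counts.
    """
    config = config or default_config()
    df = cohort.copy()
    log_rows = []

    if "dbp" in df.columns:
        high = df["dbp"] > config.dbp_ceiling
        n_high = int(high.sum())
        if n_high:
            df = df.loc[~high].reset_index(drop=True)
        log_rows.append({"rule": "dbp_ceiling", "column": "dbp",
                         "n_excluded": n_high})

    for spec in config.outcomes:
        if spec.kind != "continuous" or spec.name not in df.columns:
            continue
        col = df[spec.name].astype(float)
        if spec.transform == "log":
            nonpos = col.notna() & (col <= 0)
            n_nonpos = int(nonpos.sum())
            col = col.where(~nonpos)
            col = np.log(col)
            if n_nonpos:
                log_rows.append({"rule": "log_nonpositive", "column": spec.name,
                                 "n_excluded": n_nonpos})
        m, s = col.mean(), col.std()
        if s and np.isfinite(s) and s > 0:
            out = col.notna() & ((col - m).abs() > config.outlier_sd * s)
            n_out = int(out.sum())
            col = col.where(~out)
        else:
            n_out = 0
        log_rows.append({"rule": f"outlier_{config.outlier_sd}sd",
                         "column": spec.name, "n_excluded": n_out})
        df[spec.name] = col

    return df, pd.DataFrame(log_rows, columns=["rule", "column", "n_excluded"])


def _design(cohort: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric covariate design from the cohort's coded columns."""
    cols = {}
    for name in covariates:
        if name == "sex":
            cols["female"] = (cohort["sex"] == "female").astype(float)
        elif name == "ethnicity":
            cols["non_european"] = (cohort["ethnicity"] == "non_european").astype(float)
        elif name == "season":
            cols["cold_season"] = (cohort["season"] == "cold").astype(float)
        else:
            cols[name] = cohort[name].astype(float)
    return pd.DataFrame(cols, index=cohort.index)


_EMPTY_ROW = {
    "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
    "n": 0, "first_stage_f": np.nan, "endogeneity_p": np.nan, "skipped": None,
}


def _result_row(outcome: OutcomeSpec, method: str, **kw) -> dict:
    row = {"outcome": outcome.name, "kind": outcome.kind,
           "transform": outcome.transform, "method": method}
    row.update(_EMPTY_ROW)
    row.update(kw)
    return row


def _subset_for(df: pd.DataFrame, spec: OutcomeSpec, config: AnalysisConfig
                ) -> pd.DataFrame:
    if spec.adult_only:
        return df.loc[df["age"] >= config.adult_age]
    return df


# ---------------------------------------------------------------------------
# observational and IV analyses
# ---------------------------------------------------------------------------

def observational_analysis(cohort: pd.DataFrame,
                           config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Age/sex-adjusted regressions of each outcome on DBP, per 50 mg/l.

    Continuous outcomes: OLS slope rescaled by ``scale``.  Binary outcomes:
    logistic regression, OR = exp(scale * coefficient).
    """
    config = config or default_config()
    rows = []
    for spec in config.outcomes:
        if spec.name not in cohort.columns:
            rows.append(_result_row(spec, "observational",
                                    skipped="column absent"))
            continue
        sub = _subset_for(cohort, spec, config)
        X = _design(sub, config.covariates)
        X.insert(0, "dbp", sub["dbp"].astype(float))
        y = sub[spec.name].astype(float)
        try:
            if spec.kind == "binary":
                res = fit_logistic(y, X)
                b, se = res.params["dbp"], res.bse["dbp"]
                est = float(np.exp(config.scale * b))
                lo = float(np.exp(config.scale * (b - 1.959963984540054 * se)))
                hi = float(np.exp(config.scale * (b + 1.959963984540054 * se)))
            else:
                res = fit_linear(y, X)
                b, se = res.params["dbp"], res.bse["dbp"]
                est = config.scale * float(b)
                lo = est - 1.959963984540054 * config.scale * float(se)
                hi = est + 1.959963984540054 * config.scale * float(se)
            rows.append(_result_row(
                spec, "observational", estimate=est, ci_low=lo, ci_high=hi,
                p_value=float(res.pvalues["dbp"]), n=res.n))
        except (ValueError, SeparationError, np.linalg.LinAlgError) as exc:
            rows.append(_result_row(spec, "observational", skipped=str(exc)))
    return pd.DataFrame(rows)


def iv_analysis(cohort: pd.DataFrame,
                config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Instrumental-variable causal estimates per outcome, per 50 mg/l DBP.

    Continuous outcomes: 2SLS with the Durbin-Wu-Hausman endogeneity test.
    Binary outcomes: control-function (residual-inclusion) logistic IV.
    """
    config = config or default_config()
    rows = []
    for spec in config.outcomes:
        if spec.name not in cohort.columns:
            rows.append(_result_row(spec, "iv", skipped="column absent"))
            continue
        sub = _subset_for(cohort, spec, config)
        X = _design(sub, config.covariates)
        X.insert(0, "dbp", sub["dbp"].astype(float))
        X.insert(1, "genotype", sub["genotype"].astype(float))
        y = sub[spec.name].astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", WeakInstrumentWarning)
                if spec.kind == "binary":
                    fitted = ControlFunctionLogisticIV(
                        exposure="dbp", instrument="genotype",
                        scale=config.scale).fit(X, y)
                else:
                    fitted = TwoStageLeastSquares(
                        exposure="dbp", instrument="genotype",
                        scale=config.scale).fit(X, y)
            est = fitted.to_estimate()
            rows.append(_result_row(
                spec, "iv", estimate=est.estimate, ci_low=est.ci_low,
                ci_high=est.ci_high, p_value=est.p_value, n=est.n,
                first_stage_f=est.first_stage_f,
                endogeneity_p=(np.nan if est.endogeneity_p is None
                               else est.endogeneity_p)))
        except (ValueError, SeparationError, ZeroDivisionError,
                np.linalg.LinAlgError) as exc:
            rows.append(_result_row(spec, "iv", skipped=str(exc)))
    return pd.DataFrame(rows)


def apply_bonferroni(p_values, alpha: float = 0.05, m: int = 12
                     ) -> tuple[np.ndarray, float]:
    """Family-wise error control: flag p < alpha/m; returns (flags, threshold)."""
    if m <= 0:
        raise ValueError("number of comparisons m must be positive")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    threshold = alpha / m
    with np.errstate(invalid="ignore"):
        flags = p < threshold
    return flags, threshold


def free_25ohd(total_25ohd, dbp, albumin,
               k_dbp: float = 7e8, k_alb: float = 6e5,
               mw_dbp: float = 58_000.0, mw_alb: float = 66_400.0):
    """Calculated free 25OHD (pmol/l) by the free-hormone formula.

    ``free = total / (1 + K_alb * [albumin] + K_dbp * [DBP])`` with the
    binding-protein concentrations in mol/l (mass concentrations in mg/l
    and g/l divided by the molar masses).  ``total_25ohd`` is in nmol/l;
    the result is returned in pmol/l.
    """
    total = np.asarray(total_25ohd, dtype=float)
    dbp_v = np.asarray(dbp, dtype=float)
    alb_v = np.asarray(albumin, dtype=float)
    if (total < 0).any() or (dbp_v < 0).any() or (alb_v < 0).any():
        raise ValueError("inputs to free_25ohd must be non-negative")
    dbp_molar = dbp_v * 1e-3 / mw_dbp     # mg/l -> g/l -> mol/l
    alb_molar = alb_v / mw_alb            # g/l -> mol/l
    denom = 1.0 + k_alb * alb_molar + k_dbp * dbp_molar
    out = 1000.0 * total / denom          # nmol/l -> pmol/l
    return float(out) if out.ndim == 0 else out


def first_stage_table(cohort: pd.DataFrame,
                      config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Genotype -> DBP regressions: univariable and covariate-adjusted."""
    config = config or default_config()
    rows = []
    y = cohort["dbp"].astype(float)
    g = pd.DataFrame({"genotype": cohort["genotype"].astype(float)},
                     index=cohort.index)
    for label, X in (
        ("univariable", g),
        ("multivariate",
         pd.concat([g, _design(cohort, ["age", "sex", "ethnicity"])], axis=1)),
    ):
        res = fit_linear(y, X)
        ci = res.conf_int()
        for term in res.params.index:
            if term == "const":
                continue
            rows.append({
                "model": label, "term": term,
                "estimate": float(res.params[term]),
                "ci_low": float(ci.loc[term, "low"]),
                "ci_high": float(ci.loc[term, "high"]),
                "p_value": float(res.pvalues[term]),
                "r_squared": res.r_squared, "f_stat": res.f_stat, "n": res.n,
            })
    return pd.DataFrame(rows)


def _merge_results(obs: pd.DataFrame, iv: pd.DataFrame,
                   config: AnalysisConfig) -> pd.DataFrame:
    iv_part = iv[["outcome", "estimate", "ci_low", "ci_high", "p_value", "n",
                  "first_stage_f", "endogeneity_p", "skipped"]].rename(
        columns=lambda c: c if c == "outcome" else f"iv_{c}")
    obs_part = obs.rename(
        columns={c: f"obs_{c}" for c in
                 ("estimate", "ci_low", "ci_high", "p_value", "n", "skipped")})
    merged = obs_part.drop(columns=["method", "first_stage_f", "endogeneity_p"]
                           ).merge(iv_part, on="outcome", how="outer")
    for side in ("obs", "iv"):
        flags, thr = apply_bonferroni(merged[f"{side}_p_value"],
                                      config.alpha, config.n_comparisons)
        merged[f"{side}_significant"] = flags
    merged.attrs["bonferroni_threshold"] = config.alpha / config.n_comparisons
    return merged


def run_analysis(cohort: pd.DataFrame, config: AnalysisConfig | None = None
                 ) -> dict[str, pd.DataFrame]:
    """Full pipeline on a raw cohort table.

    Returns a dict with keys ``first_stage``, ``results`` (observational and
    IV columns side by side with Bonferroni flags), ``diagnostics`` (allele
    frequency, HWE, confounder screen) and ``exclusions``.
    """
    from .genetics import (GenotypeCounts, allele_frequency, confounder_screen,
                           hwe_test, screen_to_frame)

    config = config or default_config()
    clean, exclusions = preprocess(cohort, config)
    obs = observational_analysis(clean, config)
    iv = iv_analysis(clean, config)
    results = _merge_results(obs, iv, config)

    try:
        counts = GenotypeCounts.from_genotypes(clean["genotype"])
        chi2, hwe_p = hwe_test(counts)
        diag_rows = [
            {"metric": "effect_allele_frequency",
             "value": allele_frequency(counts)},
            {"metric": "hwe_chi2", "value": chi2},
            {"metric": "hwe_p", "value": hwe_p},
        ]
    except ValueError:
        diag_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        screen = screen_to_frame(
            confounder_screen(clean, ["age", "sex", "ethnicity", "season"],
                              config.alpha))
    try:
        first_stage = first_stage_table(clean, config)
    except (ValueError, np.linalg.LinAlgError):
        first_stage = pd.DataFrame()  # e.g. subgroup too small to fit
    return {
        "first_stage": first_stage,
        "results": results,
        "diagnostics": pd.DataFrame(diag_rows),
        "confounder_screen": screen,
        "exclusions": exclusions,
    }


def subgroup_analysis(cohort: pd.DataFrame,
                      config: AnalysisConfig | None = None,
                      threshold: float | None = None) -> dict[str, pd.DataFrame]:
    """Re-run the full pipeline in the vitamin-D-deficient subgroup.

    Restricts to participants with total 25OHD below ``threshold`` nmol/l
    (default from the config, 50 nmol/l) and recomputes the first-stage
    diagnostics on the subset.  Outcomes that cannot be modelled in the
    subset are skipped with a logged reason.
    """
    config = config or default_config()
    threshold = config.subgroup_threshold if threshold is None else threshold
    if "t25ohd" not in cohort.columns:
        raise ValueError("subgroup analysis requires the 't25ohd' column")
    subset = cohort.loc[cohort["t25ohd"].astype(float) < threshold].reset_index(drop=True)
    if subset.empty:
        empty = _merge_results(
            pd.DataFrame([_result_row(s, "observational", skipped="empty subgroup")
                          for s in config.outcomes]),
            pd.DataFrame([_result_row(s, "iv", skipped="empty subgroup")
                          for s in config.outcomes]),
            config)
        return {"first_stage": pd.DataFrame(), "results": empty,
                "diagnostics": pd.DataFrame(),
                "confounder_screen": pd.DataFrame(),
                "exclusions": pd.DataFrame(), "n_subgroup": 0}
    out = run_analysis(subset, config)
    out["n_subgroup"] = len(subset)
    return out


def render_text_table(df: pd.DataFrame, float_fmt: str = "{:.3g}") -> str:
    """Human-readable aligned-text rendering of a results table."""
    show = df.copy()
    for c in show.columns:
        if show[c].dtype.kind == "f":
            show[c] = show[c].map(
                lambda v: "" if pd.isna(v) else float_fmt.format(v))
    return show.to_string(index=False)
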