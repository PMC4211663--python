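"""Summary-statistic Mendelian randomization and power calculation.

Large GWAS consortia publish per-allele association summaries (beta, SE, n)
for single-SNP look-ups.  Given such a table for the outcomes and one
association for the exposure (SNP -> DBP), the Wald ratio converts each row
into a causal estimate per 50 mg/l of DBP, replicating the individual-level
IV analysis without participant data.  The power functions answer the
design question: how large a consortium is needed to detect a given causal
effect through an instrument explaining r^2 of the exposure variance?
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import wald_ratio

__all__ = [
    "SummaryAssoc",
    "PowerSpec",
    "read_summary_table",
    "write_summary_table",
    "replicate",
    "power_continuous",
    "power_binary",
]


@dataclass
class SummaryAssoc:
    """Per-allele association summary for one phenotype from one source."""

    phenotype: str
    source: str
    beta: float                 # per effect-allele copy (log-OR if binary)
    se: float
    p: float | None = None
    n: int | None = None
    cases: int | None = None
    controls: int | None = None
    unit: str = ""
    binary: bool = False

    def validate(self) -> None:
        if self.se is None or not np.isfinite(self.se) or self.se <= 0:
            raise ValueError(f"{self.phenotype}: SE must be positive")
        if self.p is not None and np.isfinite(self.p) and not (0 <= self.p <= 1):
            raise ValueError(f"{self.phenotype}: p must lie in [0, 1]")


_SUMMARY_COLUMNS = ["phenotype", "source", "beta", "se", "p", "n",
                    "cases", "controls", "unit", "binary"]


def read_summary_table(path: str | Path) -> list[SummaryAssoc]:
    """Read a per-SNP association table (TSV with the documented header)."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA", ""])
    required = {"phenotype", "beta", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary table lacks columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(SummaryAssoc(
            phenotype=str(r["phenotype"]),
            source=str(r.get("source", "")),
            beta=float(r["beta"]),
            se=float(r["se"]) if pd.notna(r["se"]) else np.nan,
            p=float(r["p"]) if "p" in df.columns and pd.notna(r.get("p")) else None,
            n=int(r["n"]) if "n" in df.columns and pd.notna(r.get("n")) else None,
            cases=int(r["cases"]) if "cases" in df.columns and pd.notna(r.get("cases")) else None,
            controls=int(r["controls"]) if "controls" in df.columns and pd.notna(r.get("controls")) else None,
            unit=str(r["unit"]) if "unit" in df.columns and pd.notna(r.get("unit")) else "",
            binary=bool(r["binary"]) if "binary" in df.columns and pd.notna(r.get("binary")) else False,
        ))
    return out


def write_summary_table(assocs: list[SummaryAssoc], path: str | Path) -> None:
    rows = [{c: getattr(a, c) for c in _SUMMARY_COLUMNS} for a in assocs]
    pd.DataFrame(rows, columns=_SUMMARY_COLUMNS).to_csv(
        path, sep="\t", index=False, na_rep="NA")


def replicate(assoc_table: list[SummaryAssoc], exposure_assoc: SummaryAssoc,
              alpha: float = 0.05, m: int = 12,
              scale: float = 50.0) -> pd.DataFrame:
    """Wald-ratio causal estimates for every phenotype in the table.

    Each row gets the ratio estimate per ``scale`` mg/l with delta-method
    CI, a Bonferroni significance flag at ``alpha / m``, and a
    null-consistency verdict (does the CI cover the null effect?).  Rows
    with unusable summaries carry the error message instead of an estimate.
    """
    exposure_assoc.validate()
    if exposure_assoc.beta == 0:
        raise ZeroDivisionError("exposure association beta is zero")
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    rows = []
    for a in assoc_table:
        row = {"phenotype": a.phenotype, "source": a.source, "unit": a.unit,
               "binary": a.binary, "n": a.n, "beta": a.beta, "se": a.se,
               "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
               "p_value": np.nan, "significant": False,
               "null_consistent": None, "error": None}
        try:
            a.validate()
            est = wald_ratio(a.beta, a.se, exposure_assoc.beta,
                             exposure_assoc.se, scale=scale, binary=a.binary)
            null = 1.0 if a.binary else 0.0
            row.update(
                estimate=est.estimate, ci_low=est.ci_low, ci_high=est.ci_high,
                p_value=est.p_value,
                significant=bool(est.p_value < threshold),
                null_consistent=bool(est.ci_low <= null <= est.ci_high),
            )
        except (ValueError, ZeroDivisionError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["bonferroni_threshold"] = threshold
    return report


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    """Inputs for a continuous-outcome MR power computation.

    The hypothesised causal effect may be given directly as
    ``effect_sd_units`` (change in outcome SDs per exposure SD) or as
    ``frac_of_mean`` (fractional change in the outcome mean per exposure
    SD), which requires ``outcome_mean`` and ``outcome_sd`` to standardise.
    """

    n: int
    r_squared: float            # instrument r^2 on the exposure
    effect_sd_units: float | None = None
    frac_of_mean: float | None = None
    outcome_mean: float | None = None
    outcome_sd: float | None = None
    alpha: float = 0.05

    def standardized_effect(self) -> float:
        if self.effect_sd_units is not None:
            return float(self.effect_sd_units)
        if self.frac_of_mean is None:
            raise ValueError("provide effect_sd_units or frac_of_mean")
        if not self.outcome_mean or not self.outcome_sd:
            raise ValueError(
                "frac_of_mean effects need outcome_mean and outcome_sd")
        return float(self.frac_of_mean * self.outcome_mean / self.outcome_sd)

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not (0 < self.r_squared < 1):
            raise ValueError("r_squared must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def _two_sided_power(ncp: float, alpha: float) -> float:
    z = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(-z + ncp) + stats.norm.cdf(-z - ncp))


def power_continuous(spec: PowerSpec) -> float:
    """Two-sided power of the SNP-outcome test for a continuous outcome.

    Normal approximation with non-centrality ``sqrt(n * r^2) * b`` where
    ``b`` is the causal effect in outcome SDs per exposure SD: the
    instrument transmits ``sqrt(r^2)`` of an exposure SD per instrument SD.
    """
    spec.validate()
    ncp = np.sqrt(spec.n * spec.r_squared) * abs(spec.standardized_effect())
    return _two_sided_power(float(ncp), spec.alpha)


def power_binary(cases: int, controls: int, r_squared: float,
                 odds_ratio: float, alpha: float = 0.05) -> float:
    """Two-sided power of the SNP-disease test in a case-control sample.

    On the log-OR scale the variance of the per-exposure-SD estimate is
    approximately ``(1/cases + 1/controls) / r^2`` (the per-allele variance
    ``(1/cases + 1/controls) / var(G)`` divided by the squared per-allele
    exposure effect in SD units), so the non-centrality is
    ``|log OR| * sqrt(r^2 * cases * controls / (cases + controls))``.
    """
    if cases < 1 or controls < 1:
        raise ValueError("cases and controls must be >= 1")
    if not (0 < r_squared < 1):
        raise ValueError("r_squared must lie in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    ncp = abs(np.log(odds_ratio)) * np.sqrt(
        r_squared * cases * controls / (cases + controls))
    return _two_sided_power(float(ncp), alpha)
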