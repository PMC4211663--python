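"""Instrument diagnostics: allele frequency, Hardy-Weinberg, confounder screen.

A genetic variant is a valid instrument only if it behaves like a randomly
assorted allele: genotype frequencies should follow Hardy-Weinberg
proportions (deviation flags genotyping problems) and the variant must not
be associated with the measured confounders of the exposure-outcome
relationship.  This module provides those checks for a biallelic SNP coded
as the count of the effect allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import SeparationError, fit_linear, fit_logistic

__all__ = [
    "GenotypeCounts",
    "ScreenResult",
    "allele_frequency",
    "genotype_frequencies",
    "hwe_test",
    "confounder_screen",
    "screen_to_frame",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts for a biallelic SNP (AA, AC, CC)."""

    n_aa: int
    n_ac: int
    n_cc: int

    def __post_init__(self):
        if min(self.n_aa, self.n_ac, self.n_cc) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.total < 1:
            raise ValueError("total genotype count must be >= 1")

    @property
    def total(self) -> int:
        return self.n_aa + self.n_ac + self.n_cc

    @classmethod
    def from_genotypes(cls, genotypes) -> "GenotypeCounts":
        g = np.asarray(genotypes, dtype=float)
        g = g[np.isfinite(g)]
        return cls(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))


def allele_frequency(counts: GenotypeCounts) -> float:
    """Sample frequency of the effect (C) allele."""
    return (counts.n_ac + 2 * counts.n_cc) / (2 * counts.total)


def genotype_frequencies(counts: GenotypeCounts) -> tuple[float, float, float]:
    """Observed genotype frequencies (AA, AC, CC)."""
    n = counts.total
    return counts.n_aa / n, counts.n_ac / n, counts.n_cc / n


def hwe_test(counts: GenotypeCounts) -> tuple[float, float]:
    """Chi-square test for deviation from Hardy-Weinberg equilibrium.

    Compares observed genotype counts to the (1-p)^2 : 2p(1-p) : p^2
    expectation at the sample allele frequency; one degree of freedom, no
    continuity correction.  Returns ``(statistic, p_value)``.
    """
    p = allele_frequency(counts)
    n = counts.total
    expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    observed = np.array([counts.n_aa, counts.n_ac, counts.n_cc], dtype=float)
    nz = expected > 0
    statistic = float(np.sum((observed[nz] - expected[nz]) ** 2 / expected[nz]))
    return statistic, float(stats.chi2.sf(statistic, df=1))


@dataclass
class ScreenResult:
    """Association of one potential confounder with the instrument."""

    covariate: str
    estimate: float     # per effect-allele copy (log-odds for binary covariates)
    p_value: float
    associated: bool


#: Covariates screened by default when present in the cohort table.
DEFAULT_SCREEN_COVARIATES = [
    "age", "sex", "ethnicity", "season", "education", "sunlight", "smoking",
]

_BINARY_POSITIVE = {"sex": "female", "ethnicity": "non_european", "season": "cold"}


def confounder_screen(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
) -> list[ScreenResult]:
    """Regress each candidate confounder on the effect-allele count.

    Continuous covariates use a linear model, binary ones a logistic model.
    ``associated`` is ``p < alpha`` (unadjusted: the screen is diagnostic).
    Covariates absent from the table are skipped with a warning.
    """
    if "genotype" not in cohort.columns:
        raise ValueError("cohort lacks a 'genotype' column")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    covariates = DEFAULT_SCREEN_COVARIATES if covariates is None else covariates
    g = cohort["genotype"].to_numpy(dtype=float)
    results: list[ScreenResult] = []
    for name in covariates:
        if name not in cohort.columns:
            warnings.warn(f"confounder screen: column {name!r} absent, skipped",
                          stacklevel=2)
            continue
        col = cohort[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            positive = _BINARY_POSITIVE.get(name)
            levels = col.dropna().unique()
            if positive is None:
                if len(levels) != 2:
                    warnings.warn(
                        f"confounder screen: {name!r} is non-binary categorical, "
                        "skipped", stacklevel=2)
                    continue
                positive = sorted(levels)[0]
            y = (col == positive).astype(float).where(col.notna()).to_numpy()
        else:
            y = col.to_numpy(dtype=float)
        vals = y[np.isfinite(y)]
        binary = np.all(np.isin(vals, [0.0, 1.0]))
        try:
            if binary:
                res = fit_logistic(y, pd.DataFrame({"genotype": g}))
            else:
                res = fit_linear(y, pd.DataFrame({"genotype": g}))
        except (ValueError, SeparationError) as exc:
            warnings.warn(f"confounder screen: {name!r} skipped ({exc})",
                          stacklevel=2)
            continue
        est = float(res.params["genotype"])
        p = float(res.pvalues["genotype"])
        results.append(ScreenResult(name, est, p, bool(p < alpha)))
    return results


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"covariate": r.covariate, "estimate": r.estimate,
          "p_value": r.p_value, "associated": r.associated} for r in results]
    )
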