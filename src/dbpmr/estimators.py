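"""Regression and instrumental-variable estimators.

The two IV estimators are implemented as scikit-learn-style estimator
classes so they compose with sklearn pipelines and model selection:

``TwoStageLeastSquares``
    Classic just-identified/over-identified 2SLS for continuous outcomes,
    with structural-residual (not naive second-stage) standard errors, the
    first-stage partial F of the instrument, and the Durbin-Wu-Hausman
    endogeneity statistic in its augmented-regression (Durbin score) form.

``ControlFunctionLogisticIV``
    Two-stage residual inclusion for binary outcomes: a linear first stage
    of the exposure on the instrument, then a logistic second stage of the
    outcome on the fitted exposure, covariates, and the first-stage
    residual.  The Wald CI treats the first stage as fixed and is therefore
    approximate.

Module-level functions (``two_stage_least_squares``, ``durbin_wu_hausman``,
``control_function_logistic``, ``wald_ratio``, ``fit_linear``,
``fit_logistic``) are thin wrappers over these classes and statsmodels.
Effects are reported per ``scale`` mg/l of exposure (default 50, one
population SD of DBP); binary-outcome effects are odds ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "FitResult",
    "IVEstimate",
    "SeparationError",
    "WeakInstrumentWarning",
    "fit_linear",
    "fit_logistic",
    "TwoStageLeastSquares",
    "ControlFunctionLogisticIV",
    "two_stage_least_squares",
    "durbin_wu_hausman",
    "control_function_logistic",
    "wald_ratio",
    "f_from_r2",
]

Z975 = float(stats.norm.ppf(0.975))


class SeparationError(RuntimeError):
    """Logistic fit failed because of (quasi-)complete separation."""


class WeakInstrumentWarning(UserWarning):
    """First-stage partial F of the instrument is below the threshold."""


@dataclass
class FitResult:
    """Output of a single regression fit."""

    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    pvalues: pd.Series
    n: int
    r_squared: float | None = None
    f_stat: float | None = None
    loglike: float | None = None
    df_resid: float | None = None

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"low": lo, "high": hi})


@dataclass
class IVEstimate:
    """A causal effect estimate per `scale` mg/l of exposure."""

    estimate: float              # trait difference, or OR for binary outcomes
    ci_low: float
    ci_high: float
    p_value: float
    se: float                    # on the estimation scale (log-OR for binary)
    n: int
    method: str
    scale: float = 50.0
    binary: bool = False
    first_stage_f: float | None = None
    endogeneity_p: float | None = None
    messages: list[str] = field(default_factory=list)


def f_from_r2(r_squared: float, n: int, n_predictors: int = 1) -> float:
    """Overall F implied by the coefficient of determination.

    For one predictor this is the exact identity
    ``F = (r^2 / (1 - r^2)) * (n - 2)``.
    """
    if not (0.0 <= r_squared < 1.0):
        raise ValueError("r_squared must lie in [0, 1)")
    k = n_predictors
    return (r_squared / k) / ((1.0 - r_squared) / (n - k - 1))


# ---------------------------------------------------------------------------
# design-matrix plumbing
# ---------------------------------------------------------------------------

def _as_frame(X, default_prefix: str = "x") -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"{default_prefix}{i}" for i in range(X.shape[1])])


def _complete_cases(y: np.ndarray, *mats: np.ndarray) -> np.ndarray:
    mask = np.isfinite(y)
    for m in mats:
        mask &= np.all(np.isfinite(m), axis=1)
    return mask


def _check_rank(X: np.ndarray, names) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix is rank-deficient (columns: {list(names)})")


# ---------------------------------------------------------------------------
# plain fits (statsmodels-backed)
# ---------------------------------------------------------------------------

def fit_linear(y, X, add_intercept: bool = True) -> FitResult:
    """Ordinary least squares of ``y`` on the columns of ``X`` (complete case)."""
    Xf = _as_frame(X)
    yv = np.asarray(y, dtype=float)
    Xv = Xf.to_numpy(dtype=float)
    mask = _complete_cases(yv, Xv)
    yv, Xv = yv[mask], Xv[mask]
    names = list(Xf.columns)
    if add_intercept:
        Xv = np.column_stack([np.ones(len(yv)), Xv])
        names = ["const"] + names
    if len(yv) < Xv.shape[1] + 2:
        raise ValueError(
            f"too few complete cases ({len(yv)}) for {Xv.shape[1]} parameters"
        )
    _check_rank(Xv, names)
    res = sm.OLS(yv, Xv).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(res.rsquared)
        fval = float(res.fvalue)
    if not np.isfinite(r2):
        r2, fval = 0.0, np.nan  # degenerate (e.g. constant) outcome
    idx = pd.Index(names)
    return FitResult(
        params=pd.Series(res.params, index=idx),
        bse=pd.Series(res.bse, index=idx),
        cov_params=pd.DataFrame(res.cov_params(), index=idx, columns=idx),
        pvalues=pd.Series(res.pvalues, index=idx),
        n=int(res.nobs),
        r_squared=r2,
        f_stat=fval,
        df_resid=float(res.df_resid),
    )


_SEPARATION_PARAM_BOUND = 1e3  # |slope| beyond this on a standardized design => separation


def fit_logistic(y, X, add_intercept: bool = True) -> FitResult:
    """Maximum-likelihood logistic regression (complete case, Wald SEs)."""
    Xf = _as_frame(X)
    yv = np.asarray(y, dtype=float)
    Xv = Xf.to_numpy(dtype=float)
    mask = _complete_cases(yv, Xv)
    yv, Xv = yv[mask], Xv[mask]
    classes = np.unique(yv)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("outcome must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("outcome has a single class; logistic fit impossible")
    names = list(Xf.columns)
    if add_intercept:
        Xv = np.column_stack([np.ones(len(yv)), Xv])
        names = ["const"] + names
    if len(yv) < Xv.shape[1] + 2:
        raise ValueError("too few complete cases for the logistic model")
    _check_rank(Xv, names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation re-diagnosed below
        try:
            res = sm.Logit(yv, Xv).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(str(exc)) from exc
    sds = Xv.std(axis=0)
    sds[sds == 0] = 1.0
    if (not res.mle_retvals["converged"]) or np.any(
        np.abs(res.params * sds) > _SEPARATION_PARAM_BOUND
    ):
        raise SeparationError(
            "logistic fit did not converge; data are (quasi-)separated"
        )
    idx = pd.Index(names)
    return FitResult(
        params=pd.Series(res.params, index=idx),
        bse=pd.Series(res.bse, index=idx),
        cov_params=pd.DataFrame(res.cov_params(), index=idx, columns=idx),
        pvalues=pd.Series(res.pvalues, index=idx),
        n=int(res.nobs),
        loglike=float(res.llf),
        df_resid=float(res.df_resid),
    )


# ---------------------------------------------------------------------------
# two-stage least squares
# ---------------------------------------------------------------------------

class TwoStageLeastSquares(RegressorMixin, BaseEstimator):
    """Linear instrumental-variable regression (2SLS).

    Parameters
    ----------
    exposure, instrument
        Column labels (for DataFrame ``X``) or integer positions (for array
        ``X``) of the endogenous exposure and the instrument.  All remaining
        columns of ``X`` are treated as exogenous covariates.
    scale
        Report the causal effect per this many exposure units (50 mg/l, one
        population SD of DBP, by default).
    robust
        If True use heteroskedasticity-robust (sandwich) standard errors
        instead of the classic homoskedastic IV variance.
    weak_f_threshold
        Emit a :class:`WeakInstrumentWarning` when the first-stage partial F
        falls below this value (conventionally 10).

    Attributes
    ----------
    estimate_ : causal effect per ``scale`` exposure units
    ci_ : (low, high) 95% confidence interval for ``estimate_``
    p_value_ : two-sided normal-theory p-value
    first_stage_f_ : first-stage partial F of the instrument
    endogeneity_p_ : Durbin-Wu-Hausman p-value (exposure exogeneity)
    coef_, cov_ : structural coefficients (per exposure unit) and covariance
    """

    def __init__(self, exposure=0, instrument=1, scale: float = 50.0,
                 robust: bool = False, weak_f_threshold: float = 10.0):
        self.exposure = exposure
        self.instrument = instrument
        self.scale = scale
        self.robust = robust
        self.weak_f_threshold = weak_f_threshold

    # -- helpers -------------------------------------------------------
    def _split(self, X):
        Xf = _as_frame(X)
        cols = list(Xf.columns)

        def _resolve(key):
            if key in cols:
                return cols.index(key)
            if isinstance(key, (int, np.integer)) and 0 <= key < len(cols):
                return int(key)
            raise KeyError(f"column {key!r} not found in X")

        i_exp = _resolve(self.exposure)
        i_ins = _resolve(self.instrument)
        if i_exp == i_ins:
            raise ValueError("exposure and instrument must differ")
        i_cov = [i for i in range(len(cols)) if i not in (i_exp, i_ins)]
        M = Xf.to_numpy(dtype=float)
        return M[:, i_exp], M[:, i_ins], M[:, i_cov], [cols[i] for i in i_cov]

    def fit(self, X, y):
        x, z, C, cov_names = self._split(X)
        yv = np.asarray(y, dtype=float)
        mask = _complete_cases(yv, x[:, None], z[:, None], C)
        x, z, C, yv = x[mask], z[mask], C[mask], yv[mask]
        n = len(yv)
        k = 2 + C.shape[1]
        if n < k + 2:
            raise ValueError(f"too few complete cases ({n}) for {k} parameters")
        if np.ptp(z) == 0:
            raise ValueError("instrument is constant; IV estimation impossible")

        ones = np.ones(n)
        Z = np.column_stack([ones, z, C])        # instruments + exogenous
        W = np.column_stack([ones, x, C])        # structural regressors
        names = ["const", "exposure"] + cov_names
        _check_rank(Z, ["const", "instrument"] + cov_names)
        _check_rank(W, names)

        # first stage: exposure on instrument + covariates
        fs_beta, *_ = np.linalg.lstsq(Z, x, rcond=None)
        x_hat = Z @ fs_beta
        v_hat = x - x_hat
        fs_sigma2 = v_hat @ v_hat / (n - Z.shape[1])
        ZtZ_inv = np.linalg.inv(Z.T @ Z)
        fs_se = np.sqrt(fs_sigma2 * ZtZ_inv[1, 1])
        self.first_stage_f_ = float((fs_beta[1] / fs_se) ** 2)
        self.first_stage_coef_ = float(fs_beta[1])
        if self.first_stage_f_ < self.weak_f_threshold:
            warnings.warn(
                f"weak instrument: first-stage F = {self.first_stage_f_:.2f} "
                f"< {self.weak_f_threshold}",
                WeakInstrumentWarning,
                stacklevel=2,
            )

        # second stage on instrument-predicted exposure
        W_hat = np.column_stack([ones, x_hat, C])
        WhtWh = W_hat.T @ W_hat
        beta = np.linalg.solve(WhtWh, W_hat.T @ yv)

        # inference from structural residuals (y - W beta), not stage-2 ones
        u = yv - W @ beta
        bread = np.linalg.inv(WhtWh)
        if self.robust:
            meat = (W_hat * (u**2)[:, None]).T @ W_hat
            cov = bread @ meat @ bread * n / (n - k)
        else:
            sigma2 = u @ u / (n - k)
            cov = sigma2 * bread

        idx = pd.Index(names)
        self.coef_ = pd.Series(beta, index=idx)
        self.cov_ = pd.DataFrame(cov, index=idx, columns=idx)
        se = float(np.sqrt(cov[1, 1]))
        est = float(beta[1])
        self.estimate_ = est * self.scale
        self.se_ = se * self.scale
        self.ci_ = (self.estimate_ - Z975 * self.se_,
                    self.estimate_ + Z975 * self.se_)
        self.p_value_ = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else np.nan
        self.n_used_ = n

        # Durbin-Wu-Hausman endogeneity test, augmented-regression form:
        # add the first-stage residual to the OLS structural equation and
        # score-test its coefficient; chi2(1) = n * (RSS0 - RSS1) / RSS0.
        A0 = W
        b0, *_ = np.linalg.lstsq(A0, yv, rcond=None)
        rss0 = float(np.sum((yv - A0 @ b0) ** 2))
        A1 = np.column_stack([W, v_hat])
        b1, *_ = np.linalg.lstsq(A1, yv, rcond=None)
        rss1 = float(np.sum((yv - A1 @ b1) ** 2))
        self.endogeneity_stat_ = max(n * (rss0 - rss1) / rss0, 0.0)
        self.endogeneity_p_ = float(stats.chi2.sf(self.endogeneity_stat_, df=1))
        return self

    def predict(self, X):
        """Structural prediction at the *observed* exposure."""
        x, _, C, _ = self._split(X)
        W = np.column_stack([np.ones(len(x)), x, C])
        return W @ self.coef_.to_numpy()

    def to_estimate(self) -> IVEstimate:
        msgs = []
        if self.first_stage_f_ < self.weak_f_threshold:
            msgs.append(f"weak instrument (F={self.first_stage_f_:.2f})")
        return IVEstimate(
            estimate=self.estimate_, ci_low=self.ci_[0], ci_high=self.ci_[1],
            p_value=self.p_value_, se=self.se_, n=self.n_used_,
            method="2sls", scale=self.scale, binary=False,
            first_stage_f=self.first_stage_f_,
            endogeneity_p=self.endogeneity_p_, messages=msgs,
        )


# ---------------------------------------------------------------------------
# control-function logistic IV (two-stage residual inclusion)
# ---------------------------------------------------------------------------

class ControlFunctionLogisticIV(BaseEstimator):
    """Binary-outcome IV by two-stage residual inclusion.

    Stage 1 linearly regresses the exposure on the instrument and
    covariates; stage 2 is a logistic regression of the outcome on the
    stage-1 fitted exposure, the covariates, and the stage-1 residual (the
    control function, absorbing unmeasured confounding that is correlated
    with the first-stage error).  The reported effect is the odds ratio per
    ``scale`` exposure units, ``exp(scale * coefficient)``, with a Wald CI
    from the stage-2 covariance that treats stage 1 as fixed (approximate).

    ``include_residual=False`` drops the control function, reducing the
    estimator to a plain two-stage logistic regression.
    """

    def __init__(self, exposure=0, instrument=1, scale: float = 50.0,
                 include_residual: bool = True, weak_f_threshold: float = 10.0):
        self.exposure = exposure
        self.instrument = instrument
        self.scale = scale
        self.include_residual = include_residual
        self.weak_f_threshold = weak_f_threshold

    _split = TwoStageLeastSquares._split

    def fit(self, X, y):
        x, z, C, cov_names = self._split(X)
        yv = np.asarray(y, dtype=float)
        mask = _complete_cases(yv, x[:, None], z[:, None], C)
        x, z, C, yv = x[mask], z[mask], C[mask], yv[mask]
        if np.ptp(z) == 0:
            raise ValueError("instrument is constant; IV estimation impossible")

        fs = fit_linear(x, np.column_stack([z[:, None], C]))
        zcol = fs.params.index[1]
        self.first_stage_f_ = float((fs.params[zcol] / fs.bse[zcol]) ** 2)
        if self.first_stage_f_ < self.weak_f_threshold:
            warnings.warn(
                f"weak instrument: first-stage F = {self.first_stage_f_:.2f}",
                WeakInstrumentWarning, stacklevel=2,
            )
        ones = np.ones(len(yv))
        Z = np.column_stack([ones, z, C])
        beta_fs = np.linalg.lstsq(Z, x, rcond=None)[0]
        x_hat = Z @ beta_fs
        v_hat = x - x_hat
        self._fs_beta = beta_fs

        cols = {"exposure_hat": x_hat}
        for j, name in enumerate(cov_names):
            cols[name] = C[:, j]
        if self.include_residual:
            cols["fs_residual"] = v_hat
        design = pd.DataFrame(cols)
        res = fit_logistic(yv, design)
        self.stage2_ = res
        b = float(res.params["exposure_hat"])
        se = float(res.bse["exposure_hat"])
        self.coef_ = b
        self.se_ = se * self.scale
        self.odds_ratio_ = float(np.exp(self.scale * b))
        self.ci_ = (float(np.exp(self.scale * (b - Z975 * se))),
                    float(np.exp(self.scale * (b + Z975 * se))))
        self.p_value_ = float(res.pvalues["exposure_hat"])
        self.n_used_ = res.n
        return self

    def predict_proba(self, X):
        x, z, C, _ = self._split(X)
        Z = np.column_stack([np.ones(len(x)), z, C])
        x_hat = Z @ self._fs_beta
        cols = [np.ones(len(x)), x_hat]
        cols += [C[:, j] for j in range(C.shape[1])]
        if self.include_residual:
            cols.append(x - x_hat)
        eta = np.column_stack(cols) @ self.stage2_.params.to_numpy()
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def to_estimate(self) -> IVEstimate:
        msgs = []
        if self.first_stage_f_ < self.weak_f_threshold:
            msgs.append(f"weak instrument (F={self.first_stage_f_:.2f})")
        return IVEstimate(
            estimate=self.odds_ratio_, ci_low=self.ci_[0], ci_high=self.ci_[1],
            p_value=self.p_value_, se=self.se_, n=self.n_used_,
            method="control_function_logistic", scale=self.scale, binary=True,
            first_stage_f=self.first_stage_f_, messages=msgs,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def _assemble(outcome, exposure, instrument, covariates):
    y = np.asarray(outcome, dtype=float)
    cols = {"exposure": np.asarray(exposure, dtype=float),
            "instrument": np.asarray(instrument, dtype=float)}
    if covariates is not None:
        cf = _as_frame(covariates, default_prefix="c")
        for c in cf.columns:
            cols[str(c)] = cf[c].to_numpy(dtype=float)
    return pd.DataFrame(cols), y


def two_stage_least_squares(outcome, exposure, instrument, covariates=None,
                            scale: float = 50.0, robust: bool = False) -> IVEstimate:
    """2SLS causal effect of ``exposure`` on ``outcome`` per ``scale`` units."""
    X, y = _assemble(outcome, exposure, instrument, covariates)
    est = TwoStageLeastSquares(exposure="exposure", instrument="instrument",
                               scale=scale, robust=robust).fit(X, y)
    return est.to_estimate()


def durbin_wu_hausman(outcome, exposure, instrument, covariates=None
                      ) -> tuple[float, float]:
    """Durbin-Wu-Hausman endogeneity test (statistic, p); chi-square, 1 df."""
    X, y = _assemble(outcome, exposure, instrument, covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", WeakInstrumentWarning)
        est = TwoStageLeastSquares(exposure="exposure",
                                   instrument="instrument").fit(X, y)
    return est.endogeneity_stat_, est.endogeneity_p_


def control_function_logistic(disease, exposure, instrument, covariates=None,
                              scale: float = 50.0) -> IVEstimate:
    """Two-stage residual-inclusion logistic IV; returns an OR per ``scale``."""
    X, y = _assemble(disease, exposure, instrument, covariates)
    est = ControlFunctionLogisticIV(exposure="exposure", instrument="instrument",
                                    scale=scale).fit(X, y)
    return est.to_estimate()


def wald_ratio(beta_outcome: float, se_outcome: float,
               beta_exposure: float, se_exposure: float,
               scale: float = 50.0, binary: bool = False,
               n: int = 0) -> IVEstimate:
    """Single-instrument Wald-ratio causal estimate from summary statistics.

    The ratio ``beta_outcome / beta_exposure`` is rescaled to per-``scale``
    exposure units.  The SE uses the first-order delta method, ignoring the
    numerator-denominator covariance.  For ``binary=True`` the inputs are
    log-ORs and the returned estimate is an odds ratio.
    """
    if beta_exposure == 0:
        raise ZeroDivisionError("exposure association is zero; Wald ratio undefined")
    if se_outcome <= 0 or se_exposure <= 0:
        raise ValueError("standard errors must be positive")
    ratio = beta_outcome / beta_exposure * scale
    var = (se_outcome**2 / beta_exposure**2
           + beta_outcome**2 * se_exposure**2 / beta_exposure**4)
    se = scale * float(np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(ratio) / se)) if se > 0 else np.nan
    lo, hi = ratio - Z975 * se, ratio + Z975 * se
    if binary:
        return IVEstimate(estimate=float(np.exp(ratio)), ci_low=float(np.exp(lo)),
                          ci_high=float(np.exp(hi)), p_value=p, se=se, n=n,
                          method="wald_ratio", scale=scale, binary=True)
    return IVEstimate(estimate=ratio, ci_low=lo, ci_high=hi, p_value=p, se=se,
                      n=n, method="wald_ratio", scale=scale, binary=False)
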