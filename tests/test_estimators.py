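"""Regression and IV estimators: exact identities, cross-checks, recovery."""

import warnings

import numpy as np
import pandas as pd
import pytest

from dbpmr import (
    ControlFunctionLogisticIV,
    SeparationError,
    TwoStageLeastSquares,
    WeakInstrumentWarning,
    control_function_logistic,
    durbin_wu_hausman,
    f_from_r2,
    fit_linear,
    fit_logistic,
    generate_cohort,
    two_stage_least_squares,
    wald_ratio,
)
from dbpmr.cohort import camos_params


def _grouped_study_data():
    """Genotype-group DBP means with their group sizes (observed data)."""
    g = np.repeat([0.0, 1.0, 2.0], [1159, 893, 202])
    y = np.repeat([384.6, 360.7, 322.9], [1159, 893, 202])
    return g, y


class TestFitLinear:
    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        res = fit_linear(2 * x + 1, pd.DataFrame({"x": x}))
        assert res.params["x"] == pytest.approx(2.0, abs=1e-12)
        assert res.params["const"] == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_grouped_study_slope(self):
        """Regressing the observed genotype-group DBP means on allele count
        gives ~-28.1 mg/l per allele (closed-form Sxy/Sxx oracle)."""
        g, y = _grouped_study_data()
        sxx = np.sum((g - g.mean()) ** 2)
        sxy = np.sum((g - g.mean()) * (y - y.mean()))
        oracle = sxy / sxx
        res = fit_linear(y, pd.DataFrame({"genotype": g}))
        assert res.params["genotype"] == pytest.approx(oracle, rel=1e-12)
        assert oracle == pytest.approx(-28.1, abs=0.05)

    def test_f_matches_r2_identity(self):
        """For one predictor F = (r2/(1-r2)) (n-2), exactly."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        res = fit_linear(y, pd.DataFrame({"x": x}))
        assert res.f_stat == pytest.approx(
            f_from_r2(res.r_squared, res.n), rel=1e-10)

    def test_published_f_from_r2(self):
        assert f_from_r2(0.141, 2248) == pytest.approx(368.7, abs=0.5)

    def test_grouped_equals_expanded(self):
        """Repeated rows give exactly the same fit as the expanded data."""
        xg = np.array([0.0, 1.0, 2.0])
        yg = np.array([384.6, 360.7, 322.9])
        w = np.array([3, 2, 4])
        x_exp = np.repeat(xg, w)
        y_exp = np.repeat(yg, w)
        a = fit_linear(y_exp, pd.DataFrame({"x": x_exp}))
        x2 = np.concatenate([np.repeat(xg[i], w[i]) for i in range(3)])
        assert (x2 == x_exp).all()
        b = fit_linear(np.repeat(yg, w), pd.DataFrame({"x": np.repeat(xg, w)}))
        pd.testing.assert_series_equal(a.params, b.params)

    def test_rank_deficient_design_rejected(self):
        x = np.arange(10, dtype=float)
        with pytest.raises(ValueError, match="rank"):
            fit_linear(x, pd.DataFrame({"a": x, "b": 2 * x}))

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="complete cases"):
            fit_linear(np.array([1.0, 2.0]), pd.DataFrame({"x": [1.0, 2.0]}))

    def test_complete_case_drops_missing(self):
        x = np.array([0.0, 1, 2, 3, 4, 5, np.nan])
        y = 2 * x + 1
        y[2] = np.nan
        res = fit_linear(y, pd.DataFrame({"x": x}))
        assert res.n == 5


class TestFitLogistic:
    def test_two_by_two_table_odds_ratio(self):
        """Covariate-free logistic on a 2x2 table equals the cross-product
        ratio: (20*90)/(80*10) = 2.25."""
        y = np.repeat([1, 0, 1, 0], [20, 80, 10, 90])
        x = np.repeat([1.0, 1.0, 0.0, 0.0], [20, 80, 10, 90])
        res = fit_logistic(y, pd.DataFrame({"x": x}))
        assert np.exp(res.params["x"]) == pytest.approx(2.25, rel=1e-6)

    def test_null_association_odds_ratios_near_one(self):
        rng = np.random.default_rng(2)
        ors = []
        for _ in range(50):
            x = rng.normal(size=400)
            y = rng.integers(0, 2, size=400)
            ors.append(float(np.exp(fit_logistic(y, pd.DataFrame({"x": x})).params["x"])))
        assert np.mean(ors) == pytest.approx(1.0, abs=0.05)

    def test_perfect_separation_raises(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        x = np.array([1.0, 2, 3, 4, 5, 6])
        with pytest.raises(SeparationError):
            fit_logistic(y, pd.DataFrame({"x": x}))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.zeros(20), pd.DataFrame({"x": np.arange(20.0)}))

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(np.arange(20.0), pd.DataFrame({"x": np.arange(20.0)}))


def _iv_data(n=3000, seed=0, theta=0.12, conf=3.0):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, n).astype(float)
    u = rng.standard_normal(n)
    age = rng.normal(60, 10, n)
    x = 400 - 25 * g + 0.5 * age + 20 * u + rng.normal(0, 30, n)
    y = 2 + theta * x + conf * u + rng.normal(0, 5, n)
    return y, x, g, age


class TestTwoStageLeastSquares:
    def test_point_estimate_equals_wald_ratio(self):
        """Single-instrument covariate-free 2SLS is algebraically the ratio
        of the reduced-form and first-stage OLS slopes."""
        y, x, g, _ = _iv_data()
        num = fit_linear(y, pd.DataFrame({"g": g})).params["g"]
        den = fit_linear(x, pd.DataFrame({"g": g})).params["g"]
        ratio = wald_ratio(num, 1.0, den, 1.0, scale=50.0)
        iv = two_stage_least_squares(y, x, g, scale=50.0)
        assert iv.estimate == pytest.approx(ratio.estimate, abs=1e-10)

    def test_matches_reference_implementation(self):
        """Coefficients and classic IV standard errors agree with the
        statsmodels IV2SLS reference on the same data."""
        from statsmodels.sandbox.regression.gmm import IV2SLS

        y, x, g, age = _iv_data()
        n = len(y)
        mine = TwoStageLeastSquares(exposure="x", instrument="g", scale=1.0
                                    ).fit(pd.DataFrame({"x": x, "g": g,
                                                        "age": age}), y)
        ref = IV2SLS(y, np.column_stack([np.ones(n), x, age]),
                     instrument=np.column_stack([np.ones(n), g, age])).fit()
        np.testing.assert_allclose(mine.coef_.to_numpy(), ref.params,
                                   rtol=1e-9)
        np.testing.assert_allclose(np.sqrt(np.diag(mine.cov_.to_numpy())),
                                   ref.bse, rtol=1e-9)

    def test_invariant_to_instrument_recoding(self):
        """Counting the other allele flips the first-stage sign but leaves
        the causal estimate untouched."""
        y, x, g, age = _iv_data()
        cov = pd.DataFrame({"age": age})
        a = two_stage_least_squares(y, x, g, cov)
        b = two_stage_least_squares(y, x, 2 - g, cov)
        assert a.estimate == pytest.approx(b.estimate, rel=1e-9)
        assert a.first_stage_f == pytest.approx(b.first_stage_f, rel=1e-6)

    def test_agrees_with_ols_when_no_confounding(self):
        y, x, g, _ = _iv_data(n=100_000, seed=3, conf=0.0)
        iv = two_stage_least_squares(y, x, g, scale=1.0)
        ols = fit_linear(y, pd.DataFrame({"x": x}))
        se = np.sqrt(iv.se**2 + ols.bse["x"] ** 2)
        assert abs(iv.estimate - ols.params["x"]) < 3 * se

    def test_weak_instrument_warning(self):
        rng = np.random.default_rng(5)
        y, x, _, _ = _iv_data(n=500, seed=5)
        noise_instrument = rng.normal(size=500)
        with pytest.warns(WeakInstrumentWarning):
            est = two_stage_least_squares(y, x, noise_instrument)
        assert est.messages

    def test_constant_instrument_rejected(self):
        y, x, _, _ = _iv_data(n=200)
        with pytest.raises(ValueError, match="constant"):
            two_stage_least_squares(y, x, np.ones(200))

    def test_sklearn_interface(self):
        y, x, g, age = _iv_data(n=1000, seed=8)
        X = pd.DataFrame({"x": x, "g": g, "age": age})
        est = TwoStageLeastSquares(exposure="x", instrument="g")
        assert est.get_params()["scale"] == 50.0
        est.set_params(scale=1.0).fit(X, y)
        pred = est.predict(X)
        assert pred.shape == y.shape
        # structural prediction: R^2 against y should be high here
        assert np.corrcoef(pred, y)[0, 1] ** 2 > 0.5


class TestDurbinWuHausman:
    def test_statistic_non_negative(self):
        for seed in range(5):
            y, x, g, age = _iv_data(n=400, seed=seed, conf=0.0)
            stat, p = durbin_wu_hausman(y, x, g, pd.DataFrame({"age": age}))
            assert stat >= 0
            assert 0 <= p <= 1

    def test_detects_planted_endogeneity(self):
        """With strong confounding the endogeneity p-value is small in the
        clear majority of replicates."""
        hits = 0
        for seed in range(40):
            y, x, g, _ = _iv_data(n=2000, seed=100 + seed, conf=4.0)
            _, p = durbin_wu_hausman(y, x, g)
            hits += p < 0.01
        assert hits > 30


class TestControlFunctionLogistic:
    @staticmethod
    def _binary_iv_data(n, seed, theta_per50, conf=0.8, maf=0.288):
        """Triangular model: endogeneity enters through the first-stage
        error, the regime in which residual inclusion is consistent."""
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, maf, n).astype(float)
        v = rng.normal(0, 45.0, n)
        x = 400.0 - 27.6 * g + v
        eta = np.log(0.1 / 0.9) + theta_per50 / 50.0 * (x - x.mean()) + conf * v / 45.0
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return y, x, g

    def test_without_residual_reduces_to_plain_two_stage(self):
        y, x, g = self._binary_iv_data(3000, 1, np.log(0.6))
        X = pd.DataFrame({"x": x, "g": g})
        cf = ControlFunctionLogisticIV(exposure="x", instrument="g",
                                       include_residual=False).fit(X, y)
        # plain two-stage: logistic of y on the first-stage fitted values
        xhat = fit_linear(x, pd.DataFrame({"g": g}))
        fitted = xhat.params["const"] + xhat.params["g"] * g
        plain = fit_logistic(y, pd.DataFrame({"exposure_hat": fitted}))
        assert cf.coef_ == pytest.approx(float(plain.params["exposure_hat"]),
                                         rel=1e-8)

    def test_parameter_recovery_protective_effect(self):
        """Mean estimated OR over replicates recovers the true OR 0.51 per
        50 mg/l despite confounding that biases the naive fit."""
        true_or = 0.51
        log_ors, naive = [], []
        for seed in range(150):
            y, x, g = self._binary_iv_data(4000, 1000 + seed, np.log(true_or))
            est = control_function_logistic(y, x, g)
            log_ors.append(np.log(est.estimate))
            naive.append(
                50.0 * float(fit_logistic(y, pd.DataFrame({"x": x})).params["x"]))
        mc_se = np.std(log_ors, ddof=1) / np.sqrt(len(log_ors))
        assert np.mean(log_ors) == pytest.approx(np.log(true_or),
                                                 abs=3 * mc_se)
        # the naive (observational) logistic is visibly biased away
        assert abs(np.mean(naive) - np.log(true_or)) > 5 * mc_se

    def test_null_coverage_under_confounding(self, camos):
        """For the causally-null disease the IV CI covers OR 1 in ~95% of
        replicates even though the exposure is confounded."""
        assert camos.traits["diabetes"].theta == 0.0
        rng = np.random.default_rng(77)
        covered = 0
        reps = 200
        for _ in range(reps):
            cohort, _ = generate_cohort(camos, 2254, rng)
            est = control_function_logistic(
                cohort["diabetes"], cohort["dbp"], cohort["genotype"],
                pd.DataFrame({"age": cohort["age"],
                              "female": (cohort["sex"] == "female").astype(float)}))
            covered += est.ci_low <= 1.0 <= est.ci_high
        assert covered / reps == pytest.approx(0.95, abs=0.045)

    def test_separation_propagates(self):
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        x = np.array([1.0, 2, 3, 4, 5, 6])
        g = np.array([0.0, 1, 0, 1, 2, 2])
        with pytest.raises(SeparationError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", WeakInstrumentWarning)
                control_function_logistic(y, x, g)


class TestWaldRatio:
    def test_study_lookup_example(self):
        """-4.48 nmol/l per allele over -27.6 mg/l per allele, rescaled to
        50 mg/l: ~8.12 nmol/l."""
        est = wald_ratio(-4.48, 0.773, -27.6, 1.43, scale=50.0)
        assert est.estimate == pytest.approx(-4.48 / -27.6 * 50, rel=1e-12)
        assert est.estimate == pytest.approx(8.12, abs=0.01)
        assert est.ci_low < est.estimate < est.ci_high

    def test_zero_numerator(self):
        est = wald_ratio(0.0, 0.5, -27.6, 1.43)
        assert est.estimate == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(1.0, 0.5, 0.0, 1.0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(1.0, 0.0, 2.0, 1.0)

    def test_delta_method_se(self):
        b_out, se_out, b_exp, se_exp = -4.48, 0.773, -27.6, 1.43
        est = wald_ratio(b_out, se_out, b_exp, se_exp, scale=50.0)
        oracle = 50 * np.sqrt(se_out**2 / b_exp**2
                              + b_out**2 * se_exp**2 / b_exp**4)
        assert est.se == pytest.approx(oracle, rel=1e-12)
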