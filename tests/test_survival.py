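"""Model fitting, Breslow baseline and standardized survival curves."""

import numpy as np
import pytest
from lifelines import NelsonAalenFitter
from scipy.optimize import minimize_scalar

from marginalize.datasets import BinaryDataset, SurvivalDataset
from marginalize.survival import (
    ModelFit,
    StepCurve,
    breslow_baseline,
    fit_cox,
    fit_logistic,
    intercept_only_cox,
    standardized_survival,
)

from conftest import two_by_two


class TestStepCurve:
    def test_right_continuity(self):
        c = StepCurve(np.array([1.0, 2.0]), np.array([0.5, 0.9]), value_before_first=0.0)
        assert c(0.999) == 0.0
        assert c(1.0) == 0.5  # jumps belong to the right
        assert c(1.5) == 0.5
        assert c(2.0) == 0.9

    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError):
            StepCurve(np.array([2.0, 1.0]), np.array([1.0, 2.0]))


class TestLogistic:
    def test_two_by_two_closed_form(self):
        a, b, c, d = 20, 30, 25, 25
        fit = fit_logistic(two_by_two(a, b, c, d), adjust=False)
        assert fit.exposure_coef == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_degenerate_outcome_raises(self):
        data = BinaryDataset(np.ones(10, dtype=int),
                             np.array([0, 1] * 5), np.zeros((10, 1)))
        with pytest.raises(ValueError, match="single value"):
            fit_logistic(data)

    def test_constant_exposure_raises(self):
        data = BinaryDataset(np.array([0, 1] * 5), np.ones(10, dtype=int),
                             np.zeros((10, 1)))
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(data)

    def test_perfect_separation_raises(self):
        c = np.linspace(-2, 2, 40)
        y = (c > 0).astype(int)
        x = np.tile([0, 1], 20)
        with pytest.raises(ValueError, match="separat"):
            fit_logistic(BinaryDataset(y, x, c))


def _log_partial_likelihood(beta, data):
    """Hand-written Cox log partial likelihood (no ties in the toy data)."""
    ll = 0.0
    for i in range(data.n):
        if data.event[i] != 1:
            continue
        at_risk = data.time >= data.time[i]
        ll += beta * data.exposure[i] - np.log(
            np.sum(np.exp(beta * data.exposure[at_risk]))
        )
    return ll


class TestCox:
    def test_matches_brute_force_partial_likelihood(self, toy_survival):
        res = minimize_scalar(
            lambda b: -_log_partial_likelihood(b, toy_survival),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        for engine in ("auto", "lifelines"):
            fit = fit_cox(toy_survival, adjust=False, with_baseline=False, engine=engine)
            assert fit.exposure_coef == pytest.approx(res.x, abs=1e-4)

    def test_fast_and_lifelines_engines_agree_on_tied_data(self):
        rng = np.random.default_rng(1)
        t = np.repeat(np.arange(1.0, 21.0), 30)  # heavy ties
        e = rng.integers(0, 2, len(t))
        x = rng.integers(0, 2, len(t))
        d = SurvivalDataset(t, e, x, np.zeros((len(t), 0)))
        fast = fit_cox(d, adjust=False, with_baseline=False).exposure_coef
        ll = fit_cox(d, adjust=False, with_baseline=False, engine="lifelines").exposure_coef
        assert fast == pytest.approx(ll, abs=1e-8)

    def test_no_events_raises(self):
        d = SurvivalDataset(np.arange(1.0, 5.0), np.zeros(4, dtype=int),
                            np.array([0, 1, 0, 1]), np.zeros((4, 0)))
        with pytest.raises(ValueError, match="no events"):
            fit_cox(d)

    def test_constant_exposure_raises(self, toy_survival):
        d = SurvivalDataset(toy_survival.time, toy_survival.event,
                            np.ones(6, dtype=int), toy_survival.covariates)
        with pytest.raises(ValueError, match="constant"):
            fit_cox(d)

    def test_monotone_likelihood_raises(self):
        # all events in the exposed arm: coefficient diverges
        t = np.arange(1.0, 9.0)
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        d = SurvivalDataset(t, e, x, np.zeros((8, 0)))
        with pytest.raises(ValueError):
            fit_cox(d, adjust=False, with_baseline=False)


class TestBreslow:
    def test_null_fit_is_nelson_aalen(self, tte_rct_data):
        curve = intercept_only_cox(tte_rct_data).baseline_cumhaz
        naf = NelsonAalenFitter().fit(tte_rct_data.time, tte_rct_data.event)
        for t in (1.0, 3.0, 7.0):
            assert curve(t) == pytest.approx(
                float(naf.predict(t)), rel=1e-6
            )

    def test_hand_computed_risk_sets(self):
        # three events; jumps are d_k / sum_{at risk} exp(beta * x_i)
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        x = np.array([1, 0, 1, 0])
        d = SurvivalDataset(t, e, x, np.zeros((4, 0)))
        beta = 0.5
        fit = ModelFit(kind="cox", exposure_coef=beta, covariate_coefs=np.empty(0))
        curve = breslow_baseline(fit, d, adjust=False)
        r = np.exp(beta)
        j1 = 1 / (2 * r + 2)       # risk set {1,2,3,4}
        j2 = 1 / (r + 2)           # risk set {2,3,4}
        j3 = 1 / 1.0               # risk set {4}
        np.testing.assert_allclose(curve.values, np.cumsum([j1, j2, j3]))

    def test_contract_nondecreasing_zero_at_origin(self, tte_rct_data):
        fit = fit_cox(tte_rct_data, adjust=True)
        curve = fit.baseline_cumhaz
        assert curve(0.0) == 0.0
        assert np.all(np.diff(curve.values) >= 0)


class TestStandardizedSurvival:
    def test_no_covariates_gives_plain_exponential_form(self, tte_rct_data):
        fit = fit_cox(tte_rct_data, adjust=False)
        for x in (0, 1):
            curve = standardized_survival(fit, tte_rct_data, x)
            expected = np.exp(
                -fit.baseline_cumhaz.values * np.exp(fit.exposure_coef * x)
            )
            np.testing.assert_allclose(curve.values, expected, rtol=1e-12)

    def test_treated_curve_below_untreated_for_positive_effect(self, tte_rct_data):
        fit = fit_cox(tte_rct_data, adjust=True)
        assert fit.exposure_coef > 0
        s0 = standardized_survival(fit, tte_rct_data, 0)
        s1 = standardized_survival(fit, tte_rct_data, 1)
        assert np.all(s1.values <= s0.values + 1e-15)
        assert s0.value_before_first == 1.0
        assert np.all(np.diff(s0.values) <= 1e-15)

    def test_point_mass_weights_reproduce_subject_curve(self, tte_rct_data):
        fit = fit_cox(tte_rct_data, adjust=True)
        w = np.zeros(tte_rct_data.n)
        w[3] = 1.0
        curve = standardized_survival(fit, tte_rct_data, 1, weights=w)
        lp = fit.exposure_coef + tte_rct_data.covariates[3] @ fit.covariate_coefs
        np.testing.assert_allclose(
            curve.values, np.exp(-fit.baseline_cumhaz.values * np.exp(lp)), rtol=1e-12
        )

    def test_negative_weights_rejected(self, tte_rct_data):
        fit = fit_cox(tte_rct_data, adjust=True)
        w = np.ones(tte_rct_data.n)
        w[0] = -1.0
        with pytest.raises(ValueError, match="nonnegative"):
            standardized_survival(fit, tte_rct_data, 0, weights=w)
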