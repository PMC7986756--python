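"""Characteristic collapsibility functions and the integration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from marginalize.ccf import (
    LINKS,
    RateModelSpec,
    ccf_eval,
    classify_ccf,
    marginal_effect_by_integration,
    rate_ccf_eval,
)


@settings(derandomize=True, max_examples=60)
@given(
    name=st.sampled_from(sorted(LINKS)),
    p=st.floats(min_value=0.001, max_value=0.999),
)
def test_link_inverse_roundtrip(name, p):
    link = LINKS[name]
    assert link.inverse(link.forward(p)) == pytest.approx(p, abs=1e-12)


@settings(derandomize=True, max_examples=40)
@given(name=st.sampled_from(sorted(LINKS)))
def test_link_forward_strictly_monotone(name):
    link = LINKS[name]
    p = np.linspace(0.01, 0.99, 200)
    d = np.diff(link.forward(p))
    assert np.all(d > 0) or np.all(d < 0)


class TestCcfEval:
    def test_worked_logistic_example(self):
        # the untreated probability 0.047 maps to ~0.330 under a conditional
        # odds ratio of 10 (the exact-model pair is 0.047 -> 0.332)
        assert ccf_eval("logit", np.log(10), 0.047) == pytest.approx(0.330, abs=5e-4)

    def test_logit_closed_form(self):
        # g(x) = 10x / (1 + 9x)
        assert ccf_eval("logit", np.log(10), 0.5) == pytest.approx(10 * 0.5 / (1 + 9 * 0.5))

    @pytest.mark.parametrize("nu,p", [(0.2, 0.3), (-0.15, 0.9), (1.0, 0.05)])
    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_identity_link_is_a_shift(self, nu, p):
        assert ccf_eval("identity", nu, p) == pytest.approx(p + nu)

    def test_rejects_p_outside_unit_interval(self):
        for p in (0.0, 1.0, -0.2, 1.4):
            with pytest.raises(ValueError):
                ccf_eval("logit", 1.0, p)

    def test_warns_when_result_leaves_unit_interval(self):
        with pytest.warns(RuntimeWarning):
            out = ccf_eval("log", 1.0, 0.8)
        assert out == pytest.approx(0.8 * np.e)


@pytest.mark.parametrize(
    "link,nu,expected",
    [
        ("logit", np.log(10), "concave"),
        ("logit", -1.0, "convex"),
        ("logit", 0.0, "linear"),
        ("cloglog", 1.0, "concave"),
        ("cloglog", -0.7, "convex"),
        ("probit", 1.0, "concave"),
        ("log", 2.0, "linear"),
        ("identity", 0.3, "linear"),
        ("complementary-log", 1.0, "linear"),
    ],
)
def test_classify_ccf(link, nu, expected):
    assert classify_ccf(link, nu) == expected


class TestRateCcf:
    def test_first_interval_reduces_to_plain_ccf(self):
        # no conditioning on past survival before the first interval
        for link in ("identity", "log"):
            spec = RateModelSpec(tau=8, interval_index=1, link=link, lam=0.4)
            p0 = 0.05
            with np.errstate(all="ignore"):
                expected = ccf_eval(link, 0.4, p0)
            assert rate_ccf_eval(spec, p0) == pytest.approx(expected)

    def test_identity_null_effect_is_identity_map(self):
        spec = RateModelSpec(tau=16, interval_index=9, link="identity", lam=0.0)
        p0 = spec.baseline_rates[8] * np.prod(1 - spec.baseline_rates[:8])
        assert rate_ccf_eval(spec, p0) == pytest.approx(p0)

    def test_log_link_matches_brute_force_enumeration(self):
        # oracle: direct product of per-interval survival probabilities
        tau, l, rate, lam = 64, 32, 0.02, 0.5
        r0 = np.full(tau, rate)
        r1 = r0 * np.exp(lam)
        p0 = r0[l - 1] * np.prod(1 - r0[: l - 1])
        p1_expected = r1[l - 1] * np.prod(1 - r1[: l - 1])
        spec = RateModelSpec(tau=tau, interval_index=l, link="log", lam=lam,
                             baseline_rates=r0)
        assert rate_ccf_eval(spec, p0) == pytest.approx(p1_expected, rel=1e-12)

    def test_treated_rate_outside_unit_interval_names_interval(self):
        spec = RateModelSpec(tau=4, interval_index=2, link="identity", lam=0.5,
                             baseline_rates=[0.1, 0.6, 0.1, 0.1])
        with pytest.raises(ValueError, match="interval 2"):
            spec.treated_rates()

    def test_log_rate_model_converges_to_cloglog_risk_ccf(self):
        # proportional-hazards limit: as tau grows, cumulative risks obey
        # F1 = 1 - (1 - F0)^{exp(lam)}, the cloglog-link CCF
        tau, lam = 4000, 0.5
        spec = RateModelSpec(tau=tau, interval_index=1, link="log", lam=lam)
        r0, r1 = np.asarray(spec.baseline_rates), spec.treated_rates()
        half = tau // 2
        f0 = 1 - np.prod(1 - r0[:half])
        f1 = 1 - np.prod(1 - r1[:half])
        assert f1 == pytest.approx(ccf_eval("cloglog", lam, f0), abs=2e-4)


class TestIntegrationOracle:
    def test_marginal_odds_ratio_of_worked_example(self):
        # C ~ U(-10, 10), conditional OR 10 -> marginal OR about 1.6
        log_or = marginal_effect_by_integration(
            "logit", 0.0, np.log(10), 1.0, stats.uniform(-10, 20)
        )
        assert np.exp(log_or) == pytest.approx(1.60, abs=5e-3)

    def test_null_conditional_effect_is_collapsible(self):
        assert marginal_effect_by_integration(
            "logit", 0.0, 0.0, 1.0, stats.norm(0, 1)
        ) == pytest.approx(0.0, abs=1e-9)

    def test_binary_scenario_marginal_log_or(self):
        # exact marginal log OR implied by the (1,1) generating model; the
        # finite-sample estimator mean in the simulation study is ~0.87
        val = marginal_effect_by_integration("logit", 1.0, 1.0, 1.0, stats.norm(0, 1))
        assert val == pytest.approx(0.8606, abs=1e-3)

    @pytest.mark.parametrize("link", ["logit", "cloglog", "probit"])
    def test_attenuation_for_nonlinear_links(self, link):
        nu = 1.2
        marg = marginal_effect_by_integration(link, 0.0, nu, 1.0, stats.norm(0, 1))
        assert 0.0 < marg < nu

    @pytest.mark.parametrize("link", ["logit", "cloglog", "probit"])
    def test_no_covariate_effect_means_collapsible(self, link):
        nu = 0.8
        marg = marginal_effect_by_integration(link, -0.3, nu, 0.0, stats.norm(0, 1))
        assert marg == pytest.approx(nu, abs=1e-8)

    @pytest.mark.parametrize(
        "link,intercept,nu,coef",
        [("identity", 0.3, 0.1, 0.05), ("log", -3.0, 0.5, 0.3)],
    )
    def test_identity_and_log_links_are_collapsible(self, link, intercept, nu, coef):
        marg = marginal_effect_by_integration(
            link, intercept, nu, coef, stats.uniform(-1, 2)
        )
        assert marg == pytest.approx(nu, abs=1e-8)
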