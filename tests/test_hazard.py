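"""Simulation-based marginalization of conditional hazard ratios."""

import numpy as np
import pytest

from marginalize import ScenarioSpec, simulate_tte
from marginalize.datasets import SurvivalDataset
from marginalize.hazard import (
    MarginalHRConfig,
    SimulatedArmData,
    draw_times_from_curve,
    event_time_grid,
    fit_censoring_model,
    marginal_log_hr,
    overlay_censoring,
)
from marginalize.survival import ModelFit, StepCurve, fit_cox


class TestEventTimeGrid:
    def test_untied_times_unchanged(self):
        t = np.array([3.0, 1.0, 2.0])
        np.testing.assert_array_equal(event_time_grid(t), np.sort(t))

    def test_ties_are_perturbed_to_strict_order(self):
        rng = np.random.default_rng(0)
        t = np.array([1.0, 2.0, 2.0, 2.0, 5.0])
        grid = event_time_grid(t, rng)
        assert np.all(np.diff(grid) > 0)
        np.testing.assert_allclose(grid, np.sort(t), atol=1e-8)


class TestDrawTimes:
    def test_flat_unit_curve_censors_everyone(self):
        curve = StepCurve(np.array([1.0, 2.0]), np.array([1.0, 1.0]), 1.0)
        arm = draw_times_from_curve(curve, curve.times, 100, np.random.default_rng(0))
        assert arm.events.sum() == 0
        assert np.all(arm.times == 2.0)

    def test_single_interval_event_fraction(self):
        m = 100_000
        curve = StepCurve(np.array([1.0]), np.array([0.3]), 1.0)
        arm = draw_times_from_curve(curve, curve.times, m, np.random.default_rng(1))
        se = np.sqrt(0.7 * 0.3 / m)
        assert arm.events.mean() == pytest.approx(0.7, abs=3 * se)

    def test_samplers_are_distributionally_equivalent(self):
        m = 100_000
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        s = np.array([0.9, 0.7, 0.55, 0.4, 0.35])
        curve = StepCurve(times, s, 1.0)
        counts = {}
        for sampler in ("inverse_transform", "bernoulli_chain"):
            arm = draw_times_from_curve(
                curve, times, m, np.random.default_rng(7), sampler
            )
            counts[sampler] = np.array(
                [np.sum((arm.times == t) & (arm.events == 1)) for t in times]
                + [np.sum(arm.events == 0)]
            )
        q = np.append(-np.diff(np.append(1.0, s)), s[-1])
        se = np.sqrt(2 * m * q * (1 - q))
        diff = np.abs(counts["inverse_transform"] - counts["bernoulli_chain"])
        assert np.all(diff <= 3.5 * se)

    def test_increasing_curve_rejected(self):
        curve = StepCurve(np.array([1.0, 2.0]), np.array([0.5, 0.8]), 1.0)
        with pytest.raises(ValueError, match="increasing"):
            draw_times_from_curve(curve, curve.times, 10, np.random.default_rng(0))

    def test_zero_survival_before_final_grid_time_rejected(self):
        curve = StepCurve(np.array([1.0, 2.0, 3.0]), np.array([0.5, 0.0, 0.0]), 1.0)
        with pytest.raises(ValueError, match="zero"):
            draw_times_from_curve(curve, curve.times, 10, np.random.default_rng(0))


class TestOverlay:
    def _arm(self, times, events, x=0):
        return SimulatedArmData(np.asarray(times, float), np.asarray(events), x)

    def test_late_censoring_leaves_event_arm_unchanged(self):
        ev = self._arm([1.0, 2.0], [1, 0])
        cs = self._arm([9.0, 9.0], [1, 1])
        out = overlay_censoring(ev, cs)
        np.testing.assert_array_equal(out.times, ev.times)
        np.testing.assert_array_equal(out.events, ev.events)

    def test_earlier_censoring_wins(self):
        out = overlay_censoring(self._arm([4.0], [1]), self._arm([3.0], [1]))
        assert out.times[0] == 3.0 and out.events[0] == 0

    def test_grid_end_censoring_stays_censoring(self):
        # the 'event time' was itself a censoring: indicator must remain 0
        out = overlay_censoring(self._arm([4.0], [0]), self._arm([5.0], [1]))
        assert out.times[0] == 4.0 and out.events[0] == 0

    def test_mismatched_arms_rejected(self):
        with pytest.raises(ValueError):
            overlay_censoring(self._arm([1.0], [1]), self._arm([1.0, 2.0], [1, 1]))
        with pytest.raises(ValueError):
            overlay_censoring(self._arm([1.0], [1], x=0), self._arm([1.0], [1], x=1))


class TestCensoringModel:
    def test_flipped_indicator_counts(self, tte_rct_data):
        fit = fit_censoring_model(tte_rct_data)
        assert fit.n_events == tte_rct_data.n - tte_rct_data.n_events

    def test_common_admin_censoring_gives_single_step(self):
        t = np.array([1.0, 2.0, 3.0, 5.0, 5.0, 5.0, 5.0, 5.0])
        e = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        x = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        d = SurvivalDataset(t, e, x, np.zeros((8, 1)))
        fit = fit_censoring_model(d, adjust=False)
        assert len(fit.baseline_cumhaz.times) == 1
        assert fit.baseline_cumhaz.times[0] == 5.0

    def test_no_censored_subjects_raises_with_guidance(self):
        t = np.arange(1.0, 7.0)
        d = SurvivalDataset(t, np.ones(6, dtype=int),
                            np.array([0, 1] * 3), np.zeros((6, 1)))
        with pytest.raises(ValueError, match="censoring='none'"):
            fit_censoring_model(d)

    def test_independent_censoring_recovers_null_coefficients(self):
        # administrative censoring does not depend on exposure or covariate
        spec = ScenarioSpec.from_label("tte", "(1,1)", n=5000, seed=21)
        d = simulate_tte(spec)
        fit = fit_censoring_model(d)
        assert abs(fit.exposure_coef) < 0.2
        assert abs(fit.covariate_coefs[0]) < 0.15


class TestMarginalLogHR:
    def test_null_conditional_effect_gives_null_marginal(self, tte_rct_data):
        fit = fit_cox(tte_rct_data, adjust=True)
        null_fit = ModelFit(
            kind="cox", exposure_coef=0.0, covariate_coefs=fit.covariate_coefs,
            baseline_cumhaz=fit.baseline_cumhaz,
            n_subjects=fit.n_subjects, n_events=fit.n_events,
        )
        est = marginal_log_hr(
            tte_rct_data, MarginalHRConfig(m=20_000, seed=5), conditional_fit=null_fit
        )
        assert est.estimate == pytest.approx(0.0, abs=0.05)

    def test_covariate_free_fit_recovers_unadjusted_coefficient(self, tte_rct_data):
        # with no covariates S1 = S0^{exp(lam)}: the marginal PH model is
        # exact and the simulated fit must return the plain Cox coefficient
        unadj = fit_cox(tte_rct_data, adjust=False)
        est = marginal_log_hr(
            tte_rct_data,
            MarginalHRConfig(m=100_000, seed=9, censoring="none"),
            conditional_fit=unadj,
        )
        # ~2 Monte-Carlo SEs at m = 1e5 (SE ~ sqrt(4 / #simulated events))
        mc_se = np.sqrt(4.0 / est.meta["n_simulated_events"])
        assert est.estimate == pytest.approx(unadj.exposure_coef, abs=2 * mc_se)

    def test_mimic_and_admin_only_agree_under_admin_censoring(self, tte_rct_data):
        ests = {
            mode: marginal_log_hr(
                tte_rct_data, MarginalHRConfig(m=20_000, seed=13, censoring=mode)
            ).estimate
            for mode in ("mimic", "admin_only")
        }
        assert ests["mimic"] == pytest.approx(ests["admin_only"], abs=0.05)

    def test_attenuation_relative_to_conditional(self, tte_rct_data):
        cond = fit_cox(tte_rct_data, adjust=True)
        est = marginal_log_hr(
            tte_rct_data, MarginalHRConfig(m=20_000, seed=3), conditional_fit=cond
        )
        assert 0.0 < est.estimate < cond.exposure_coef

    def test_longer_time_frame_than_study_rejected(self, tte_rct_data):
        cfg = MarginalHRConfig(m=100, time_frame=99.0)
        with pytest.raises(ValueError, match="time frame|time_frame"):
            marginal_log_hr(tte_rct_data, cfg)

    def test_handles_duplicate_times_from_resampling(self, tte_rct_data):
        # bootstrap resamples duplicate event times exactly; the grid must
        # still be strictly increasing and the procedure must run
        idx = np.random.default_rng(2).integers(0, tte_rct_data.n, tte_rct_data.n)
        est = marginal_log_hr(tte_rct_data.subset(idx), MarginalHRConfig(m=1000, seed=1))
        assert np.isfinite(est.estimate)

    def test_seed_reproducibility(self, tte_rct_data):
        cfg = MarginalHRConfig(m=2000, seed=42)
        a = marginal_log_hr(tte_rct_data, cfg).estimate
        b = marginal_log_hr(tte_rct_data, cfg).estimate
        assert a == b
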