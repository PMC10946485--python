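"""Likelihood, fitting, and model functions of the flexible parametric model."""

import numpy as np
import pytest

from temporecal import (
    SimulationConfig,
    cumulative_hazard,
    fit_fpm,
    hazard,
    loglik,
    simulate_cohort,
    survival,
)
from temporecal.fpm import CompetingRisksModel, InsufficientEventsError
from temporecal.splines import SplineSpec
from conftest import exponential_model, make_cohort, weibull_model


def exponential_cohort(n, rate, seed, censor_at=10.0):
    cfg = SimulationConfig(n=n, K=1, scale=(rate,), shape=(1.0,), trend=(0.0,),
                           beta=({},), covariate_spec=(),
                           diagnosis_span=(2000.0, 2000.0),
                           study_end=2000.0 + censor_at, seed=seed)
    return simulate_cohort(cfg)


class TestLoglik:
    def test_exponential_closed_form(self):
        cohort = exponential_cohort(400, 0.2, seed=1)
        model = exponential_model(1, 0.2)
        d = cohort.data
        n_events = int((d["status"] == 1).sum())
        person_time = float((d["exit"] - d["entry"]).sum())
        expected = n_events * np.log(0.2) - 0.2 * person_time
        assert loglik(model, cohort, 1) == pytest.approx(expected, rel=1e-12)

    def test_left_truncation_term_by_term(self):
        # three subjects, one truncated: ll = full-interval ll + survival-to-entry
        cohort = make_cohort([0.0, 2.0, 0.0], [3.0, 5.0, 4.0], [1, 1, 0], K=1)
        rate = 0.3
        model = exponential_model(1, rate)
        by_hand = 0.0
        for entry, exit_, d in [(0, 3, 1), (2, 5, 1), (0, 4, 0)]:
            if d:
                by_hand += np.log(rate)
            by_hand += -rate * exit_ + rate * entry
        assert loglik(model, cohort, 1) == pytest.approx(by_hand, rel=1e-12)

    def test_other_cause_events_are_censored(self):
        cohort = make_cohort([0, 0], [2.0, 3.0], [1, 2])
        model = exponential_model(1, 0.2)
        as_censored = make_cohort([0, 0], [2.0, 3.0], [1, 0])
        assert loglik(model, cohort, 1) == pytest.approx(
            loglik(exponential_model(1, 0.2), as_censored, 1))

    def test_negative_slope_at_event_gives_minus_inf(self):
        cohort = make_cohort([0], [2.0], [1], K=1)
        spec = SplineSpec(knots=(np.log(0.05), np.log(20.0)))
        bad = exponential_model(1, 0.2)
        bad.gamma = np.array([np.log(0.2), -1.0])  # decreasing cumulative hazard
        assert loglik(bad, cohort, 1) == -np.inf


class TestFitting:
    def test_exponential_rate_recovered(self):
        cohort = exponential_cohort(20000, 0.2, seed=4)
        fit = fit_fpm(cohort, 1, df=1)
        assert cumulative_hazard(fit, 1.0) == pytest.approx(0.2, rel=0.02)
        assert fit.gamma[1] == pytest.approx(1.0, rel=0.02)

    def test_weibull_covariate_effect_within_three_se(self):
        cfg = SimulationConfig(
            n=10000, K=1, scale=(0.15,), shape=(1.3,), trend=(0.0,),
            beta=({"x1": 0.5},),
            covariate_spec=({"name": "x1", "kind": "binary", "p": 0.5},),
            diagnosis_span=(2000.0, 2000.0), study_end=2008.0, seed=5)
        cohort = simulate_cohort(cfg)
        fit = fit_fpm(cohort, 1, df=2)
        beta = fit.beta_dict()["x1"]
        se = fit.fit_info["beta_se"]["x1"]
        assert abs(beta - 0.5) < 3 * se
        assert se < 0.1

    def test_fixed_beta_held_exactly(self):
        cfg = SimulationConfig(
            n=2000, K=1, scale=(0.2,), shape=(1.0,), trend=(0.0,),
            beta=({"x1": 0.5},),
            covariate_spec=({"name": "x1", "kind": "binary", "p": 0.5},),
            diagnosis_span=(2000.0, 2000.0), study_end=2008.0, seed=6)
        cohort = simulate_cohort(cfg)
        fit = fit_fpm(cohort, 1, df=2, fixed_beta={"x1": 0.5})
        assert fit.beta_dict()["x1"] == 0.5
        assert fit.constrained[fit.beta_names.index("x1")]

    def test_constrained_at_free_optimum_reproduces_gamma(self):
        cfg = SimulationConfig(
            n=3000, K=1, scale=(0.2,), shape=(0.9,), trend=(0.0,),
            beta=({"x1": 0.4},),
            covariate_spec=({"name": "x1", "kind": "binary", "p": 0.4},),
            diagnosis_span=(2000.0, 2000.0), study_end=2008.0, seed=7)
        cohort = simulate_cohort(cfg)
        free = fit_fpm(cohort, 1, df=2)
        constrained = fit_fpm(cohort, 1, df=2,
                              fixed_beta=free.beta_dict(), knots=free.spline)
        assert np.allclose(constrained.gamma, free.gamma, atol=1e-5)

    def test_optimum_beats_perturbations(self):
        cohort = exponential_cohort(1000, 0.3, seed=8)
        fit = fit_fpm(cohort, 1, df=2)
        best = loglik(fit, cohort, 1)
        rng = np.random.default_rng(0)
        import copy
        for _ in range(10):
            other = copy.deepcopy(fit)
            other.gamma = fit.gamma + rng.normal(0, 0.05, fit.gamma.size)
            assert loglik(other, cohort, 1) <= best + 1e-9

    def test_insufficient_events_raises(self):
        cohort = make_cohort([0, 0, 0], [1.0, 2.0, 3.0], [1, 0, 0], K=1)
        with pytest.raises(InsufficientEventsError):
            fit_fpm(cohort, 1, df=3)

    def test_event_counts_recorded(self):
        cohort = exponential_cohort(500, 0.2, seed=9)
        fit = fit_fpm(cohort, 1, df=1)
        assert fit.fit_info["n_events"] == int((cohort.data["status"] == 1).sum())
        assert fit.fit_info["n_subjects"] == 500


class TestModelFunctions:
    def test_exponential_hazard_constant(self):
        model = exponential_model(1, 0.2)
        ts = np.array([0.5, 1.0, 3.0, 7.0])
        assert np.allclose(hazard(model, ts), 0.2)

    def test_weibull_hazard_shape(self):
        model = weibull_model(1, 0.3, 1.7)
        # h(t) = scale * p * t^(p-1)
        ts = np.array([0.5, 2.0, 5.0])
        assert np.allclose(hazard(model, ts), 0.3 * 1.7 * ts ** 0.7)

    def test_hazard_matches_numerical_derivative_of_H(self):
        cohort = exponential_cohort(2000, 0.25, seed=10)
        fit = fit_fpm(cohort, 1, df=3)
        grid = np.linspace(0.5, 8.0, 25)
        h = 1e-5
        num = (cumulative_hazard(fit, grid + h) - cumulative_hazard(fit, grid - h)) / (2 * h)
        assert np.allclose(hazard(fit, grid), num, rtol=1e-5)

    def test_time_zero_boundary_values(self):
        model = exponential_model(1, 0.2)
        assert cumulative_hazard(model, 0.0) == 0.0
        assert survival(model, 0.0) == 1.0
        assert cumulative_hazard(model, 2.0) == pytest.approx(0.4)

    def test_fitted_survival_strictly_decreasing(self):
        cohort = exponential_cohort(2000, 0.25, seed=11)
        fit = fit_fpm(cohort, 1, df=3)
        grid = np.linspace(0.1, 9.0, 200)
        s = survival(fit, grid)
        assert np.all(np.diff(s) < 0)

    def test_hazard_rejects_nonpositive_time(self):
        with pytest.raises(ValueError):
            hazard(exponential_model(1, 0.2), 0.0)


class TestSerialization:
    def test_round_trip_reproduces_predictions(self, tmp_path):
        cfg = SimulationConfig(n=2000, seed=12)
        cohort = simulate_cohort(cfg)
        from temporecal import fit_standard, predict_cif
        model = fit_standard(cohort, 2)
        path = tmp_path / "model.json"
        model.save(path)
        again = CompetingRisksModel.load(path)
        x = {"stage_adv": 1.0, "age_c": 0.3}
        p1 = predict_cif(model, x, [1.0, 5.0])
        p2 = predict_cif(again, x, [1.0, 5.0])
        assert np.allclose(p1.cif, p2.cif, atol=1e-12)
        flags = {b["name"]: b["constrained"] for m in again.to_dict()["models"]
                 for b in m["beta"]}
        assert not any(flags.values())
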