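"""Calibration-in-the-large, calibration curves, ICI, and concordance."""

import numpy as np
import pytest

from temporecal import (
    CalibrationCurve,
    aalen_johansen,
    assess_calibration,
    calibration_curve,
    calibration_in_the_large,
    cif_concordance,
    default_scenario,
    fit_standard,
    ici,
    predict_cif,
    pseudo_values,
    simulate_cohort,
    simulate_validation_cohort,
)


@pytest.fixture(scope="module")
def fitted_pair():
    cfg = default_scenario(n=4000, seed=40)
    dev = simulate_cohort(cfg)
    val = simulate_validation_cohort(cfg, 2005.0, 10.0, n=2000, seed=41)
    return fit_standard(dev, 2), val


class TestCalibrationInTheLarge:
    def test_difference_is_predicted_minus_observed(self, fitted_pair):
        model, val = fitted_pair
        out = calibration_in_the_large(model, val, 5.0, B=0)
        for key in (1, 2, "all"):
            entry = out[key]
            assert entry["difference"] == pytest.approx(
                entry["predicted"] - entry["observed"], abs=1e-12)

    def test_all_cause_difference_sums_causes(self, fitted_pair):
        model, val = fitted_pair
        out = calibration_in_the_large(model, val, 5.0, B=0)
        # predicted all-cause = sum of cause CIFs; observed 1-KM = sum of AJ CIFs
        assert out["all"]["predicted"] == pytest.approx(
            out[1]["predicted"] + out[2]["predicted"], abs=1e-9)
        assert out["all"]["observed"] == pytest.approx(
            out[1]["observed"] + out[2]["observed"], abs=1e-9)

    def test_observed_matches_aalen_johansen(self, fitted_pair):
        model, val = fitted_pair
        out = calibration_in_the_large(model, val, 5.0, B=0)
        est = aalen_johansen(val)
        assert out[1]["observed"] == pytest.approx(est.cif_at(1, 5.0))
        assert out["all"]["observed"] == pytest.approx(est.all_cause_risk_at(5.0))

    def test_bootstrap_interval_contains_point_estimate(self, fitted_pair):
        model, val = fitted_pair
        out = calibration_in_the_large(model, val, 5.0, B=100, seed=2)
        for key in (1, 2, "all"):
            lo, hi = out[key]["ci"]
            assert lo <= out[key]["difference"] <= hi

    def test_bootstrap_deterministic_given_seed(self, fitted_pair):
        model, val = fitted_pair
        a = calibration_in_the_large(model, val, 5.0, B=60, seed=7)
        b = calibration_in_the_large(model, val, 5.0, B=60, seed=7)
        assert a == b


class TestCalibrationCurve:
    def test_constant_pseudo_values_give_flat_curve(self):
        rng = np.random.default_rng(1)
        pred = rng.uniform(0.1, 0.6, 200)
        curve = calibration_curve(pred, np.full(200, 0.3), span=0.2)
        assert np.allclose(curve.observed, 0.3)

    def test_perfect_calibration_recovered_from_indicators(self):
        # predicted risk == true risk; pseudo-values are event indicators
        rng = np.random.default_rng(2)
        n = 5000
        pred = rng.uniform(0.05, 0.95, n)
        pv = (rng.uniform(size=n) < pred).astype(float)
        curve = calibration_curve(pred, pv, span=0.1)
        assert ici(pred, curve) < 0.03

    def test_uniform_shift_detected_by_ici(self):
        rng = np.random.default_rng(3)
        n = 5000
        true = rng.uniform(0.1, 0.6, n)
        pv = (rng.uniform(size=n) < true).astype(float)
        shifted = true + 0.05
        curve = calibration_curve(shifted, pv, span=0.1)
        assert ici(shifted, curve) == pytest.approx(0.05, abs=0.015)

    def test_window_is_rank_symmetric_local_mean(self):
        pred = np.linspace(0.1, 0.9, 21)
        pv = np.arange(21, dtype=float)
        curve = calibration_curve(pred, pv, span=0.25)   # k = 5
        # interior rank r averages pv ranks r-2..r+2 = pv[r]
        assert np.allclose(curve.observed[2:-2], pv[2:-2])
        # truncated edge windows average the first/last k ranks
        assert curve.observed[0] == pytest.approx(np.mean(pv[:5]))
        assert curve.observed[-1] == pytest.approx(np.mean(pv[-5:]))

    def test_input_validation(self):
        pred = np.linspace(0.1, 0.9, 30)
        with pytest.raises(ValueError):
            calibration_curve(pred[:10], np.zeros(10))       # too few
        with pytest.raises(ValueError):
            calibration_curve(pred, np.zeros(29))            # length mismatch
        with pytest.raises(ValueError):
            calibration_curve(pred + 0.5, np.zeros(30))      # risks above 1
        with pytest.raises(ValueError):
            calibration_curve(pred, np.zeros(30), span=0.0)

    def test_ici_zero_for_identity_curve(self):
        pred = np.linspace(0.05, 0.5, 50)
        curve = CalibrationCurve(predicted=pred, observed=pred.copy(), span=0.3)
        assert ici(pred, curve) == 0.0


class TestConcordance:
    def test_brute_force_oracle(self, fitted_pair):
        model, val = fitted_pair
        small = val.subset(np.arange(120))
        tau = 5.0
        c = cif_concordance(model, small, 1, tau)
        # exhaustive pair loop
        d = small.data
        f = predict_cif(model, small, [tau]).cif[0, :, 0]
        exit_, status = d["exit"].to_numpy(), d["status"].to_numpy()
        num = den = 0.0
        n = len(d)
        for i in range(n):
            if not (status[i] == 1 and exit_[i] < tau):
                continue
            for j in range(n):
                if i == j:
                    continue
                if exit_[j] > exit_[i] or status[j] == 2:
                    den += 1
                    num += 1.0 if f[i] > f[j] else (0.5 if f[i] == f[j] else 0.0)
        assert c == pytest.approx(num / den, abs=1e-12)

    def test_better_than_random_on_informative_model(self, fitted_pair):
        model, val = fitted_pair
        assert cif_concordance(model, val, 1, 5.0) > 0.55

    def test_tau_beyond_followup_rejected(self, fitted_pair):
        model, val = fitted_pair
        with pytest.raises(ValueError):
            cif_concordance(model, val, 1, 99.0)


class TestAssessCalibration:
    def test_report_consistent_with_components(self, fitted_pair):
        model, val = fitted_pair
        report = assess_calibration(model, val, 5.0, B=0, seed=0)
        direct = calibration_in_the_large(model, val, 5.0, B=0)
        assert report.cal_large == direct
        assert set(report.ici) == {1, 2, "all"}
        assert report.concordance[1] == pytest.approx(
            cif_concordance(model, val, 1, 5.0))
        # observed RLYL matches the nonparametric estimate directly
        from temporecal import restricted_life_years_lost
        est = aalen_johansen(val)
        assert report.rlyl_observed == restricted_life_years_lost(est, 5.0)

    def test_ici_matches_manual_pseudo_value_curve(self, fitted_pair):
        model, val = fitted_pair
        report = assess_calibration(model, val, 5.0, B=0, with_concordance=False)
        grid = np.linspace(5.0 / 32, 5.0, 32)
        pred = predict_cif(model, val, grid).at(5.0)[0][0]
        pv = pseudo_values(val, 5.0, ("cause", 1))
        curve = calibration_curve(pred, pv, span=0.3)
        assert report.ici[1] == pytest.approx(ici(pred, curve), abs=1e-12)

    def test_json_round_trip(self, fitted_pair, tmp_path):
        import json
        model, val = fitted_pair
        report = assess_calibration(model, val, 5.0, B=0, with_concordance=False)
        path = tmp_path / "report.json"
        report.save(path)
        loaded = json.load(open(path))
        assert loaded["horizon"] == 5.0
        assert loaded["ici"]["1"] == pytest.approx(report.ici[1])

    def test_plot_writes_file(self, fitted_pair, tmp_path):
        from temporecal import plot_calibration
        model, val = fitted_pair
        report = assess_calibration(model, val, 5.0, B=0, with_concordance=False)
        out = tmp_path / "cal.png"
        plot_calibration(report, out)
        assert out.stat().st_size > 0
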