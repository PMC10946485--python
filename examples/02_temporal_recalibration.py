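"""Why temporal recalibration: a standard fit over-predicts recent risk.

When survival improves over calendar time, a model fitted to all diagnosis
years averages old (higher) and new (lower) hazard levels, so it over-predicts
risk for newly diagnosed patients.  Period analysis fits everything inside a
recent calendar window; temporal recalibration keeps the full-data predictor
effects and re-estimates only the baseline inside the window.
"""

from temporecal import (
    PeriodWindow,
    aalen_johansen,
    default_scenario,
    fit_period,
    fit_standard,
    fit_temporal_recalibration,
    predict_cif,
    simulate_cohort,
    simulate_validation_cohort,
)

cfg = default_scenario(n=4000, seed=1)
dev = simulate_cohort(cfg)
window = PeriodWindow(2002.0, 2005.0)

standard = fit_standard(dev, 3)
period = fit_period(dev, 3, window)
recal = fit_temporal_recalibration(dev, 3, window, base_model=standard)

# validation: patients diagnosed in the scenario's final year
val = simulate_validation_cohort(cfg, validation_year=2005.0,
                                 followup_years=10.0, seed=2)
obs = aalen_johansen(val)
horizon = 5.0
print(f"observed 5-year cancer risk (Aalen-Johansen): "
      f"{obs.cif_at(1, horizon):.3f}")
for name, model in [("standard", standard), ("period", period),
                    ("temporal recalibration", recal)]:
    mean_pred = predict_cif(model, val, [horizon]).cif[0, :, 0].mean()
    gap = mean_pred - obs.cif_at(1, horizon)
    print(f"{name:>23}: mean predicted {mean_pred:.3f} "
          f"(calibration-in-the-large {gap:+.3f})")

# recalibration leaves the predictor effects untouched, so single-model risk
# rankings are identical to the standard fit's
assert (recal[1].beta == standard[1].beta).all()
print("recalibrated coefficients identical to the standard fit: True")
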