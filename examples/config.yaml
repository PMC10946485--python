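# Configuration for the temporecal command line: a full pipeline on the
# default trended scenario.  Run, from the repository root:
#
#   temporecal simulate --config examples/config.yaml --out scratch/data
#   temporecal fit      --config examples/config.yaml \
#       --data scratch/data/development.csv --out scratch/model.json
#   temporecal predict  --config examples/config.yaml --model scratch/model.json \
#       --data scratch/data/validation.csv --out scratch/predictions.csv
#   temporecal validate --config examples/config.yaml --model scratch/model.json \
#       --data scratch/data/validation.csv --out scratch/calibration --plots

K: 2
covariates:
  - {name: stage_adv, kind: continuous}   # already 0/1 in the simulated data
  - {name: age_c, kind: continuous}

strategy:
  name: temporal_recalibration            # standard | period | temporal_recalibration
  df: 3                                   # spline degrees of freedom per cause
  window: {start: 2002.0, end: 2005.0}    # recent calendar window [start, end)

horizons: [5.0]
bootstrap: 200                            # resamples for calibration intervals
span: 0.3                                 # calibration-curve smoother span
seed: 1

simulation:
  n: 4000
  validation: {year: 2005.0, followup: 10.0, n: 4000}
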