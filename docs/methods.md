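# Methods

Statistical background for `temporecal`, in the notation used throughout the
code. Subjects are indexed by i, causes of death by k = 1, …, K; each subject
carries an entry time (0 unless left-truncated), an exit time, a status
(0 censored, k = cause-k death), and a diagnosis calendar year `dx_year`.

## Cause-specific flexible parametric models

Each cause gets its own fully parametric survival model on the
log-cumulative-hazard scale:

    ln H_k(t | x) = γ_{k0} + s_k(ln t; γ_k) + β_k' x,

where s_k is a restricted cubic spline in log time and β_k' x is the linear
predictor. The spline basis (`splines.py`) is the truncated-power restricted
cubic basis: with knots k_min = k_1 < … < k_m = k_max,

    v_1(u) = u,
    v_j(u) = (u − k_j)_+^3 − λ_j (u − k_min)_+^3 − (1 − λ_j)(u − k_max)_+^3,
    λ_j = (k_max − k_j) / (k_max − k_min),      j = 2, …, m − 1,

which is linear beyond the boundary knots. A model with df degrees of freedom
uses m = df + 1 knots placed at the minimum, maximum, and equally spaced
centiles of the *log event times of its own cause* (df = 5 → 20/40/60/80th
centiles). df = 1 reduces to a Weibull model.

The hazard follows by differentiation: with ζ(u) the spline part evaluated at
u = ln t,

    h_k(t | x) = H_k(t | x) · ζ'(ln t) / t,

so the model is valid only where ζ'(ln t) > 0; every fit audits monotonicity
on a grid and records the result.

### Likelihood with delayed entry

For cause k, events of other causes are censorings. With d_i the cause-k
event indicator, t_i the exit, and t0_i the entry time, the log likelihood on
the log-cumulative-hazard scale is

    ℓ_k = Σ_i d_i [ ln ζ'(ln t_i) − ln t_i + η_i ] − exp(η_i) + exp(η_i^0),

where η_i = ζ(ln t_i) + β' x_i, and η_i^0 is the same evaluated at the entry
time (the left-truncation correction; zero when entry = 0). Maximisation uses
L-BFGS-B with the analytic gradient, a smoothed log barrier against
non-positive spline slopes, and a Nelder–Mead restart if the gradient norm at
the solution is not small. Standard errors come from the inverse numerical
Hessian over the free parameters.

Holding coefficients fixed (`fixed_beta`) is implemented as a per-subject
offset: the constrained fit maximises the same likelihood over the spline
parameters only.

## Period analysis

A period window [b_start, b_end) in calendar time keeps only person-time
lived inside the window. A subject diagnosed in year y with entry e and exit
t contributes

    new entry = max(e, b_start − y),    new exit = min(t, b_end − y),

is dropped if new exit ≤ new entry, and is censored if the event falls at or
after b_end in calendar time. Refitting both baseline and coefficients on
this slice is the *period analysis* strategy: up-to-date hazard levels, fewer
events.

## Temporal recalibration

1. Fit the standard model on the full cohort → β̂_k.
2. Optionally estimate a uniform shrinkage factor per cause and scale
   β̂_k ← c_k β̂_k. The factor is the bootstrap calibration slope: refit on a
   resample, evaluate its prognostic index on the original data, fit a
   one-coefficient model with that index as the only covariate, and average
   the slope over resamples.
3. Re-estimate only the baseline spline on the period-window slice with the
   (possibly shrunken) coefficients held fixed.

The returned coefficients are bit-for-bit c_k · β̂_k, so any ranking of
subjects by a single model's predicted risk is unchanged; only absolute risk
levels move.

## Predicted cumulative incidence

The CIF combines all the cause-specific models:

    F_k(t | x) = ∫_0^t S(u | x) h_k(u | x) du,   S(u | x) = exp(−Σ_k H_k(u | x)),

and has no closed form for spline baselines. `temporecal` integrates by
composite Gauss–Legendre quadrature with panels between consecutive output
times. The first panel is subdivided geometrically toward zero because the
hazard carries an integrable singularity t^{ζ'−1} when the log-time slope is
below one; grading restores near-machine accuracy (the test suite checks the
Weibull closed form to 1e-10). By construction Σ_k F_k(t|x) + S(t|x) = 1.

The area under a CIF up to a horizon τ, ∫_0^τ F_k, is the *restricted life
years lost* to cause k by τ; the cause-wise areas decompose the total
τ − ∫_0^τ S.

## Nonparametric benchmarks

Observed risks come from the Aalen–Johansen estimator with delayed-entry risk
sets (subject at risk at t when entry < t ≤ exit):

    F̂_k(t) = Σ_{t_j ≤ t} Ŝ(t_{j−1}) d_{kj} / n_j,

with Ŝ the all-cause Kaplan–Meier. The implementation conserves
Σ_k F̂_k = 1 − Ŝ exactly at every event time.

### Pseudo-values

Subject-level "observed" outcomes under censoring use the jackknife:

    θ̂_i = n θ̂ − (n − 1) θ̂^{(−i)},

where θ̂ is the Aalen–Johansen CIF (or all-cause risk) at the horizon and
θ̂^{(−i)} leaves subject i out. Without censoring before the horizon the
pseudo-values are exactly the event indicators and their mean equals θ̂; with
earlier censoring the mean identity holds only approximately (a property the
test suite documents with a three-subject counter-example). The incremental
implementation updates all n leave-one-out estimates in O(n·m) via risk-set
decrements and matches the naive O(n²) recomputation to 1e-10.

## Calibration and discrimination

- **Calibration-in-the-large**: mean predicted risk minus the nonparametric
  observed risk at the horizon, per cause and all-cause, with percentile
  bootstrap intervals (predictions are fixed per subject; resampling
  recomputes both the mean prediction and the Aalen–Johansen estimate).
- **Calibration curve**: pseudo-values smoothed against predicted risk by a
  symmetric nearest-neighbour local mean (window = span·n subjects, forced
  odd, truncated at the edges). No clipping before averaging — pseudo-values
  legitimately fall outside [0, 1].
- **ICI**: mean absolute difference between the smoothed observed risk and
  the predicted risk over subjects.
- **Concordance**: a comparable pair has i dying of the cause of interest at
  t_i < τ while j is still event-free at t_i or has already died of a
  competing cause; the pair is concordant when i's predicted CIF at τ is
  larger (ties ½). No censoring weights are applied, so the index is the
  naive comparable-pairs version.

## Registry simulator

Latent cause-specific times are Weibull with a log-linear calendar trend:

    h_k(t) = λ_k p_k t^{p_k − 1} exp(β_k' x + δ_k (dx_year − y_ref)),

drawn by inverse transform from H_k(T) = E, E ~ Exp(1); the earliest latent
time and its cause are recorded, with administrative censoring at the study
end. Negative δ_k makes survival improve over calendar time — the condition
temporal recalibration addresses. The same hazards integrated by
high-accuracy quadrature (`analytic_cif`) provide exact truth for testing;
the default scenario's parameters are frozen study conditions used by the
acceptance battery.
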