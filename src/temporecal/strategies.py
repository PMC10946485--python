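"""Model-development strategies for trending survival: standard fit, period
analysis, and temporal recalibration.

*Standard*: every subject informs both predictor effects and baseline,
regardless of diagnosis year — early, higher-mortality patients drag the
baseline upward when survival is improving.

*Period analysis*: both predictor effects and baseline are estimated on the
follow-up accrued inside a recent calendar window (delayed entry for subjects
diagnosed earlier), so the hazard level is up to date but the effective number
of events shrinks.

*Temporal recalibration*: predictor effects come from the full data; only the
baseline log cumulative hazard spline is re-estimated inside the window with
the predictor coefficients held fixed (optionally after uniform shrinkage).
The returned coefficients are identical to the standard fit's, so single-model
risk orderings are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .cohort import Cohort, PeriodWindow, apply_period_window
from .fpm import CompetingRisksModel, ConvergenceError, fit_fpm, InsufficientEventsError

__all__ = [
    "StrategySpec",
    "fit_standard",
    "fit_period",
    "fit_temporal_recalibration",
    "fit_strategy",
    "uniform_shrinkage",
]

log = logging.getLogger(__name__)

STRATEGIES = ("standard", "period", "temporal_recalibration")


@dataclass(frozen=True)
class StrategySpec:
    """Declarative description of one model-development strategy."""

    name: str
    df: int | tuple[int, ...] = 3
    window: PeriodWindow | None = None
    shrinkage: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.name not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, got {self.name!r}")
        if (self.window is None) != (self.name == "standard"):
            raise ValueError(
                f"strategy '{self.name}' {'must not' if self.name == 'standard' else 'must'}"
                " carry a period window"
            )


def _df_list(df, K: int) -> list[int]:
    if np.isscalar(df):
        return [int(df)] * K
    df = list(df)
    if len(df) != K:
        raise ValueError(f"need one df per cause ({K}), got {len(df)}")
    return [int(d) for d in df]


def fit_standard(cohort: Cohort, df_per_cause, covariates=None) -> CompetingRisksModel:
    """Unconstrained cause-specific fits on the full cohort."""
    dfs = _df_list(df_per_cause, cohort.K)
    models = [fit_fpm(cohort, k, dfs[k - 1], covariates=covariates)
              for k in range(1, cohort.K + 1)]
    return CompetingRisksModel(models=models, covariate_schema=cohort.schema)


def _windows_list(window, window_per_cause, K: int) -> list[PeriodWindow]:
    if window_per_cause is not None:
        wins = list(window_per_cause)
        if len(wins) != K:
            raise ValueError(f"need one window per cause ({K})")
        return wins
    return [window] * K


def fit_period(cohort: Cohort, df_per_cause, window: PeriodWindow,
               window_per_cause=None, covariates=None) -> CompetingRisksModel:
    """Unconstrained fits on the period-window slice (delayed entry).

    Different windows may be used per cause when the causes' event counts are
    very unbalanced.
    """
    dfs = _df_list(df_per_cause, cohort.K)
    wins = _windows_list(window, window_per_cause, cohort.K)
    models = []
    for k in range(1, cohort.K + 1):
        sliced = apply_period_window(cohort, wins[k - 1])
        try:
            models.append(fit_fpm(sliced, k, dfs[k - 1], covariates=covariates))
        except InsufficientEventsError as err:
            counts = sliced.event_counts()
            raise InsufficientEventsError(
                f"period window {wins[k - 1]} leaves too few cause-{k} events "
                f"(counts {counts}): {err}"
            ) from err
    return CompetingRisksModel(models=models, covariate_schema=cohort.schema)


def fit_temporal_recalibration(
    cohort: Cohort,
    df_per_cause,
    window: PeriodWindow,
    shrinkage=None,
    window_per_cause=None,
    covariates=None,
    base_model: CompetingRisksModel | None = None,
    reuse_knots: bool = False,
) -> CompetingRisksModel:
    """Two-step temporal recalibration of each cause-specific model.

    Step 1 fits the standard model on the full cohort (or reuses
    ``base_model``); step 2 optionally multiplies each cause's coefficients by
    a uniform shrinkage factor; step 3 re-estimates only the baseline spline
    on the period-window slice with the (possibly shrunken) coefficients held
    fixed.  Knots for the recalibration step are re-placed from the in-window
    event times by default because the sliced risk sets have different
    event-time support; ``reuse_knots=True`` keeps the full-data knots
    instead (useful for sensitivity analysis).
    """
    dfs = _df_list(df_per_cause, cohort.K)
    wins = _windows_list(window, window_per_cause, cohort.K)
    if base_model is None:
        base_model = fit_standard(cohort, df_per_cause, covariates=covariates)
    if shrinkage is not None:
        factors = list(shrinkage) if not np.isscalar(shrinkage) else [shrinkage] * cohort.K
        if len(factors) != cohort.K:
            raise ValueError(f"need one shrinkage factor per cause ({cohort.K})")
    else:
        factors = [1.0] * cohort.K

    models = []
    for k in range(1, cohort.K + 1):
        base = base_model[k]
        fixed = {name: factors[k - 1] * val
                 for name, val in zip(base.beta_names, base.beta)}
        sliced = apply_period_window(cohort, wins[k - 1])
        recal = fit_fpm(
            sliced, k, dfs[k - 1], fixed_beta=fixed,
            knots=base.spline if reuse_knots else None,
            covariates=base.beta_names,
        )
        # preserve bitwise equality with the (shrunken) standard coefficients
        recal.beta = factors[k - 1] * base.beta
        recal.fit_info["strategy"] = "temporal_recalibration"
        recal.fit_info["shrinkage"] = factors[k - 1]
        models.append(recal)
    return CompetingRisksModel(models=models, covariate_schema=cohort.schema)


def fit_strategy(cohort: Cohort, spec: StrategySpec, covariates=None) -> CompetingRisksModel:
    """Dispatch a :class:`StrategySpec` to the matching fitting routine."""
    if spec.name == "standard":
        return fit_standard(cohort, spec.df, covariates=covariates)
    if spec.name == "period":
        return fit_period(cohort, spec.df, spec.window, covariates=covariates)
    return fit_temporal_recalibration(
        cohort, spec.df, spec.window, shrinkage=spec.shrinkage,
        covariates=covariates,
    )


def uniform_shrinkage(cohort: Cohort, cause: int, df: int, B: int = 200,
                      seed: int | None = None, covariates=None) -> float:
    """Bootstrap estimate of the uniform (calibration-slope) shrinkage factor.

    For each of ``B`` bootstrap resamples the cause-specific model is refitted;
    its prognostic index (beta' x) is evaluated on the original cohort and a
    one-coefficient model with that index as sole covariate is fitted to the
    original data.  The mean slope over successful replicates estimates the
    shrinkage needed to correct optimism: values near 1 indicate minimal
    overfitting.  A degenerate resample equal to the original data gives a
    slope of exactly 1.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 50:
        log.warning("uniform_shrinkage with B = %d resamples is noisy", B)
    rng = np.random.default_rng(seed)
    cov = list(cohort.covariates) if covariates is None else list(covariates)
    n = len(cohort)
    slopes = []
    failures = 0
    for b in range(B):
        idx = rng.integers(0, n, n) if B > 1 else np.arange(n)
        sample = cohort.subset(idx)
        try:
            boot = fit_fpm(sample, cause, df, covariates=cov)
            pi = boot.linear_predictor(cohort.design_matrix(cov))
            aux = cohort.data.copy()
            aux["_pi"] = pi
            aux_cohort = Cohort(data=aux, K=cohort.K, covariates=["_pi"])
            slope_model = fit_fpm(aux_cohort, cause, df, covariates=["_pi"])
            slopes.append(float(slope_model.beta[0]))
        except (ConvergenceError, InsufficientEventsError, ValueError) as err:
            failures += 1
            log.warning("bootstrap replicate %d failed: %s", b, err)
    if failures > 0.2 * B:
        raise RuntimeError(
            f"{failures}/{B} bootstrap replicates failed; shrinkage estimate unreliable"
        )
    return float(np.mean(slopes))
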