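"""Shared fixtures: tiny hand-checkable cohorts and closed-form models."""

import numpy as np
import pandas as pd
import pytest

from temporecal.cohort import Cohort
from temporecal.fpm import CauseSpecificModel, CompetingRisksModel
from temporecal.splines import SplineSpec


def make_cohort(entry, exit_, status, dx_year=None, K=2, covs=None):
    n = len(exit_)
    data = pd.DataFrame({
        "id": np.arange(n),
        "entry": np.asarray(entry, dtype=float),
        "exit": np.asarray(exit_, dtype=float),
        "status": np.asarray(status, dtype=int),
        "dx_year": np.zeros(n) if dx_year is None else np.asarray(dx_year, float),
    })
    names = []
    if covs:
        for name, vals in covs.items():
            data[name] = np.asarray(vals, dtype=float)
            names.append(name)
    return Cohort(data=data, K=K, covariates=names)


@pytest.fixture
def four_subject_cohort():
    """Cause-1 death at 1, cause-2 death at 2, censored at 3, cause-1 death at 4."""
    return make_cohort([0, 0, 0, 0], [1, 2, 3, 4], [1, 2, 0, 1])


def exponential_model(cause: int, rate: float) -> CauseSpecificModel:
    """df = 1 model with unit log-time slope: H(t) = rate * t exactly."""
    spec = SplineSpec(knots=(np.log(0.05), np.log(20.0)))
    return CauseSpecificModel(cause=cause, spline=spec,
                              gamma=np.array([np.log(rate), 1.0]))


@pytest.fixture
def competing_exponentials():
    """Constant hazards h1 = 0.2, h2 = 0.1; CIFs have a closed form."""
    return CompetingRisksModel(models=[exponential_model(1, 0.2),
                                       exponential_model(2, 0.1)])


def weibull_model(cause: int, scale: float, shape: float) -> CauseSpecificModel:
    """df = 1 model with slope p: H(t) = scale * t^p exactly."""
    spec = SplineSpec(knots=(np.log(0.05), np.log(20.0)))
    return CauseSpecificModel(cause=cause, spline=spec,
                              gamma=np.array([np.log(scale), shape]))
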