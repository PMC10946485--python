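"""Nonparametric observed-risk estimators: Kaplan-Meier, Aalen-Johansen,
and jackknife pseudo-values.

The Aalen-Johansen estimator of the cause-k cumulative incidence is

    F_k(t) = sum_{j : t_j <= t}  S_KM(t_{j-1}) * d_kj / n_j,

where t_j are the ordered distinct death times, d_kj the cause-k deaths at
t_j, n_j the risk-set size, and S_KM the all-cause Kaplan-Meier survival.  By
construction sum_k F_k(t_j) = 1 - S_KM(t_j) exactly at every step.  Deaths are
processed before censorings at tied times, and delayed entry is supported
(a subject is at risk at t_j when entry < t_j <= exit).

Pseudo-values turn these estimators into one value per subject,

    pv_i = n * est - (n - 1) * est_without_i,

which under censoring can fall outside [0, 1]; their mean equals the
full-sample estimate exactly when no subject is censored before the horizon
(the jackknife of a plain mean) and approximately otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort

__all__ = [
    "NonparametricEstimate",
    "PseudoValueSet",
    "aalen_johansen",
    "km_all_cause_risk",
    "pseudo_values",
]


@dataclass
class NonparametricEstimate:
    """Step-function KM survival and AJ cumulative incidence estimates.

    ``times`` are the ordered distinct death times; ``km`` and ``cif`` are the
    right-continuous step values at those times (``cif`` has shape (K, m)).
    """

    times: np.ndarray
    n_risk: np.ndarray
    deaths: np.ndarray        # (K, m) per-cause counts
    km: np.ndarray
    cif: np.ndarray           # (K, m)

    @property
    def K(self) -> int:
        return self.cif.shape[0]

    def km_at(self, t):
        """All-cause KM survival at time(s) t (right-continuous)."""
        return self._eval(self.km, t, origin=1.0)

    def cif_at(self, cause: int, t):
        """Aalen-Johansen CIF for ``cause`` at time(s) t."""
        return self._eval(self.cif[cause - 1], t, origin=0.0)

    def all_cause_risk_at(self, t):
        """1 - KM: the nonparametric all-cause risk of death."""
        return 1.0 - self.km_at(t)

    def _eval(self, values: np.ndarray, t, origin: float):
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, tt, side="right") - 1
        out = np.full(tt.shape, origin)
        has = idx >= 0
        out[has] = values[idx[has]]
        return out[0] if np.ndim(t) == 0 else out

    def to_frame(self):
        import pandas as pd
        cols = {"time": self.times, "n_risk": self.n_risk}
        for k in range(self.K):
            cols[f"d_cause{k + 1}"] = self.deaths[k]
        cols["km"] = self.km
        for k in range(self.K):
            cols[f"cif_cause{k + 1}"] = self.cif[k]
        return pd.DataFrame(cols)


@dataclass
class PseudoValueSet:
    """Per-subject jackknife pseudo-values of a risk estimator at a horizon."""

    horizon: float
    target: str               # "cause<k>" or "all_cause"
    values: np.ndarray        # aligned with cohort row order
    estimate: float           # full-sample estimate at the horizon


def _arrays(cohort: Cohort):
    d = cohort.data
    return (
        d["entry"].to_numpy(dtype=float),
        d["exit"].to_numpy(dtype=float),
        d["status"].to_numpy(dtype=int),
    )


def _estimate_from_counts(times, n_risk, deaths):
    """KM and AJ steps from risk sets and per-cause death counts."""
    d_tot = deaths.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_risk > 0, d_tot / np.where(n_risk > 0, n_risk, 1.0), 0.0)
    km = np.cumprod(1.0 - frac)
    km_prev = np.concatenate([[1.0], km[:-1]])
    cif = np.cumsum(
        km_prev[None, :] * np.where(n_risk > 0, deaths / np.where(n_risk > 0, n_risk, 1.0), 0.0),
        axis=1,
    )
    return km, cif


def aalen_johansen(cohort: Cohort) -> NonparametricEstimate:
    """Kaplan-Meier and Aalen-Johansen estimates, with delayed-entry support."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    entry, exit_, status = _arrays(cohort)
    ev = status > 0
    times = np.unique(exit_[ev])
    m = times.size
    K = cohort.K
    deaths = np.zeros((K, m))
    if m:
        for k in range(1, K + 1):
            tk = exit_[status == k]
            idx = np.searchsorted(times, tk)
            np.add.at(deaths[k - 1], idx, 1.0)
        sorted_exit = np.sort(exit_)
        sorted_entry = np.sort(entry)
        n_geq_exit = len(exit_) - np.searchsorted(sorted_exit, times, side="left")
        n_geq_entry = len(entry) - np.searchsorted(sorted_entry, times, side="left")
        n_risk = (n_geq_exit - n_geq_entry).astype(float)
    else:
        n_risk = np.zeros(0)
    km, cif = _estimate_from_counts(times, n_risk, deaths)
    return NonparametricEstimate(times=times, n_risk=n_risk, deaths=deaths, km=km, cif=cif)


def km_all_cause_risk(cohort: Cohort) -> NonparametricEstimate:
    """All-cause Kaplan-Meier view: use ``.all_cause_risk_at`` for 1 - KM."""
    return aalen_johansen(cohort)


def _target_spec(target, K: int):
    if target == "all_cause":
        return "all_cause", None
    if isinstance(target, tuple) and target[0] == "cause":
        k = int(target[1])
    elif isinstance(target, str) and target.startswith("cause"):
        k = int(target.replace("cause", ""))
    elif isinstance(target, int):
        k = target
    else:
        raise ValueError(f"unknown pseudo-value target {target!r}")
    if not 1 <= k <= K:
        raise ValueError(f"cause {k} outside 1..{K}")
    return f"cause{k}", k


def _evaluate_target(times, km, cif, horizon, k):
    idx = np.searchsorted(times, horizon, side="right") - 1
    if k is None:
        return 1.0 - (km[idx] if idx >= 0 else 1.0)
    return cif[k - 1, idx] if idx >= 0 else 0.0


def pseudo_values(cohort: Cohort, horizon: float, target="all_cause",
                  method: str = "incremental") -> PseudoValueSet:
    """Jackknife pseudo-values of the AJ CIF or the all-cause KM risk.

    ``method="incremental"`` adjusts the shared risk-set and death-count
    vectors per left-out subject (O(n m) overall); ``method="naive"`` rebuilds
    the estimator from scratch for every leave-one-out sample and serves as a
    reference implementation.
    """
    entry, exit_, status = _arrays(cohort)
    n = len(exit_)
    if horizon > exit_.max():
        raise ValueError(
            f"horizon {horizon} beyond the last observed follow-up time {exit_.max()}"
        )
    base = aalen_johansen(cohort)
    name, k = _target_spec(target, cohort.K)
    theta = float(_evaluate_target(base.times, base.km, base.cif, horizon, k))

    if method == "naive":
        loo = np.empty(n)
        for i in range(n):
            sub = cohort.subset(np.arange(n) != i)
            est = aalen_johansen(sub)
            loo[i] = _evaluate_target(est.times, est.km, est.cif, horizon, k)
    elif method == "incremental":
        loo = _loo_matrix(base, entry, exit_, status, horizon, k, cohort.K)
    else:
        raise ValueError(f"unknown method {method!r}")

    values = n * theta - (n - 1) * loo
    return PseudoValueSet(horizon=float(horizon), target=name, values=values,
                          estimate=theta)


def _loo_matrix(base: NonparametricEstimate, entry, exit_, status, horizon, k, K):
    """Leave-one-out estimates for all subjects at once.

    Each subject's removal decrements the risk set on the death times it
    spanned and the death count at its own event time; the KM/AJ recursions
    are then re-run as row-wise cumulative products/sums.
    """
    keep = base.times <= horizon
    times = base.times[keep]
    m = times.size
    n = len(exit_)
    if m == 0:
        return np.zeros(n) if k is not None else np.zeros(n)

    n_risk = base.n_risk[keep]
    deaths = base.deaths[:, keep]
    d_tot = deaths.sum(axis=0)

    at_risk = (entry[:, None] < times[None, :]) & (times[None, :] <= exit_[:, None])
    n_mat = n_risk[None, :] - at_risk
    d_tot_mat = np.broadcast_to(d_tot, (n, m)).copy()
    own = np.zeros((n, m), dtype=bool)
    ev = status > 0
    if ev.any():
        idx = np.searchsorted(times, exit_[ev])
        rows = np.nonzero(ev)[0]
        inside = (idx < m) & np.isin(exit_[ev], times)
        own[rows[inside], idx[inside]] = True
    d_tot_mat -= own

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_mat > 0, d_tot_mat / np.where(n_mat > 0, n_mat, 1.0), 0.0)
    km = np.cumprod(1.0 - frac, axis=1)
    if k is None:
        return 1.0 - km[:, -1]

    d_k_mat = np.broadcast_to(deaths[k - 1], (n, m)).copy()
    d_k_mat -= own & (status == k)[:, None]
    km_prev = np.concatenate([np.ones((n, 1)), km[:, :-1]], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(n_mat > 0, km_prev * d_k_mat / np.where(n_mat > 0, n_mat, 1.0), 0.0)
    return incr.sum(axis=1)
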