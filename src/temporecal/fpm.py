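"""Flexible parametric proportional-hazards survival models.

The model represents the log cumulative cause-specific hazard as a restricted
cubic spline in log time plus a linear predictor,

    ln H_k(t | x) = gamma_0 + s(ln t; gamma) + beta' x,

so H_k(t|x) = exp(eta) and the hazard follows by the chain rule,
h_k(t|x) = H_k(t|x) * s'(ln t) / t.  Fitting maximises the standard
left-truncated right-censored log-likelihood

    sum_i d_i [ln s'(ln t_i) - ln t_i + eta_i] - exp(eta_i) + exp(eta_i at entry)

where d_i indicates an event of the target cause (deaths from competing causes
are censored for that cause's model) and the entry term vanishes for subjects
observed from time zero.  Coefficients may be held fixed at given values — the
device used by temporal recalibration, implemented as a per-subject offset so
the free-parameter machinery is identical for standard and constrained fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .cohort import Cohort
from .splines import SplineSpec, place_knots, rcs_eval, rcs_deriv

__all__ = [
    "CauseSpecificModel",
    "CompetingRisksModel",
    "loglik",
    "fit_fpm",
    "hazard",
    "cumulative_hazard",
    "survival",
    "ConvergenceError",
    "InsufficientEventsError",
]

_EPS = 1e-10  # floor under the spline slope inside the smoothed log


class ConvergenceError(RuntimeError):
    def __init__(self, msg, last_params=None, grad_norm=None):
        super().__init__(msg)
        self.last_params = last_params
        self.grad_norm = grad_norm


class InsufficientEventsError(ValueError):
    pass


@dataclass
class CauseSpecificModel:
    """Fitted log-cumulative-hazard model for one competing cause.

    ``gamma`` holds the intercept followed by the spline coefficients
    (length ``spline.df + 1``); ``beta`` the predictor log hazard ratios in
    ``beta_names`` order; ``constrained`` flags coefficients that were held
    fixed rather than estimated.
    """

    cause: int
    spline: SplineSpec
    gamma: np.ndarray
    beta_names: list[str] = field(default_factory=list)
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    constrained: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.constrained = np.asarray(self.constrained, dtype=bool)
        if self.gamma.size != self.spline.df + 1:
            raise ValueError("gamma length must equal spline df + 1")
        if self.beta.size != len(self.beta_names):
            raise ValueError("beta length must match beta_names")
        if self.constrained.size == 0:
            self.constrained = np.zeros(self.beta.size, dtype=bool)

    def beta_dict(self) -> dict[str, float]:
        return dict(zip(self.beta_names, self.beta.tolist()))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """beta' x for a design matrix aligned with ``beta_names``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.beta.size:
            raise ValueError(
                f"design matrix has {X.shape[1]} columns, model expects {self.beta.size}"
            )
        return X @ self.beta

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "cause": self.cause,
            "spline": self.spline.to_dict(),
            "gamma": self.gamma.tolist(),
            "beta": [
                {"name": n, "value": float(v), "constrained": bool(c)}
                for n, v, c in zip(self.beta_names, self.beta, self.constrained)
            ],
            "fit_info": {
                k: v for k, v in self.fit_info.items() if _json_safe(v)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CauseSpecificModel":
        names = [b["name"] for b in d["beta"]]
        return cls(
            cause=int(d["cause"]),
            spline=SplineSpec.from_dict(d["spline"]),
            gamma=np.asarray(d["gamma"], dtype=float),
            beta_names=names,
            beta=np.asarray([b["value"] for b in d["beta"]], dtype=float),
            constrained=np.asarray([b["constrained"] for b in d["beta"]], dtype=bool),
            fit_info=dict(d.get("fit_info", {})),
        )


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


@dataclass
class CompetingRisksModel:
    """One cause-specific model per competing cause, sharing a time origin."""

    models: list[CauseSpecificModel]
    covariate_schema: dict | None = None

    def __post_init__(self):
        causes = sorted(m.cause for m in self.models)
        if causes != list(range(1, len(self.models) + 1)):
            raise ValueError(f"need exactly one model per cause 1..K, got causes {causes}")
        self.models = sorted(self.models, key=lambda m: m.cause)

    @property
    def K(self) -> int:
        return len(self.models)

    def __getitem__(self, cause: int) -> CauseSpecificModel:
        return self.models[cause - 1]

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "models": [m.to_dict() for m in self.models],
            "covariate_schema": self.covariate_schema,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CompetingRisksModel":
        return cls(
            models=[CauseSpecificModel.from_dict(m) for m in d["models"]],
            covariate_schema=d.get("covariate_schema"),
        )

    @classmethod
    def load(cls, path) -> "CompetingRisksModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

class _FitData:
    """Pre-computed spline bases and design pieces for one cause-specific fit."""

    def __init__(self, cohort: Cohort, cause: int, spec: SplineSpec,
                 covariates: list[str], offset: np.ndarray | None):
        df_ = cohort.data
        self.t = df_["exit"].to_numpy(dtype=float)
        self.entry = df_["entry"].to_numpy(dtype=float)
        self.d = (df_["status"].to_numpy(dtype=int) == cause).astype(float)
        self.X = cohort.design_matrix(covariates)
        self.offset = np.zeros(len(self.t)) if offset is None else np.asarray(offset, float)
        self.spec = spec
        lnt = np.log(self.t)
        self.B = rcs_eval(spec, lnt)              # (n, df)
        self.Bd = rcs_deriv(spec, lnt)
        self.trunc = self.entry > 0
        if self.trunc.any():
            self.B0 = rcs_eval(spec, np.log(self.entry[self.trunc]))
        else:
            self.B0 = np.zeros((0, spec.df))
        self.lnt = lnt
        self.n_events = int(self.d.sum())


def _split(theta: np.ndarray, df: int):
    return theta[: df + 1], theta[df + 1:]


def _eta(fd: _FitData, gamma: np.ndarray, beta: np.ndarray):
    lp = fd.X @ beta if beta.size else 0.0
    eta = gamma[0] + fd.B @ gamma[1:] + lp + fd.offset
    eta0 = None
    if fd.trunc.any():
        lp_t = (fd.X[fd.trunc] @ beta) if beta.size else 0.0
        eta0 = gamma[0] + fd.B0 @ gamma[1:] + lp_t + fd.offset[fd.trunc]
    return eta, eta0


def _neg_loglik_grad(theta: np.ndarray, fd: _FitData):
    """Smoothed negative log-likelihood and gradient.

    Where the spline slope at an event time dips below a tiny floor the log is
    continued linearly, keeping the objective differentiable while pushing the
    optimizer back toward slopes that give a positive hazard.
    """
    gamma, beta = _split(theta, fd.spec.df)
    eta, eta0 = _eta(fd, gamma, beta)
    slope = fd.Bd @ gamma[1:]

    ev = fd.d > 0
    s_ev = slope[ev]
    low = s_ev < _EPS
    ln_s = np.empty_like(s_ev)
    ln_s[~low] = np.log(s_ev[~low])
    ln_s[low] = np.log(_EPS) + (s_ev[low] - _EPS) / _EPS
    dln_s = np.where(low, 1.0 / _EPS, 1.0 / np.where(low, 1.0, s_ev))

    # clip eta to avoid overflow in exp during wild optimizer steps
    w = np.exp(np.clip(eta, -300, 300))
    ll = np.sum(ln_s - fd.lnt[ev] + eta[ev]) - w.sum()
    if eta0 is not None:
        w0 = np.exp(np.clip(eta0, -300, 300))
        ll += w0.sum()
    else:
        w0 = None

    # gradient
    df = fd.spec.df
    g = np.zeros_like(theta)
    resid = fd.d - w                      # d(ll)/d(eta_i)
    g[0] = resid.sum()
    g[1: df + 1] = fd.B.T @ resid + fd.Bd[ev].T @ dln_s
    if beta.size:
        g[df + 1:] = fd.X.T @ resid
    if w0 is not None:
        g[0] += w0.sum()
        g[1: df + 1] += fd.B0.T @ w0
        if beta.size:
            g[df + 1:] += fd.X[fd.trunc].T @ w0
    return -ll, -g


def loglik(model: CauseSpecificModel, cohort: Cohort, cause: int,
           covariates: list[str] | None = None) -> float:
    """Left-truncated right-censored log-likelihood of ``model`` on ``cohort``.

    Events of causes other than ``cause`` count as censored.  Returns ``-inf``
    when the implied hazard is non-positive at any event time of the target
    cause (infeasible parameters).
    """
    cov = model.beta_names if covariates is None else covariates
    fd = _FitData(cohort, cause, model.spline, cov, None)
    gamma, beta = model.gamma, model.beta
    slope = fd.Bd @ gamma[1:]
    if np.any(slope[fd.d > 0] <= 0):
        return -np.inf
    eta, eta0 = _eta(fd, gamma, beta)
    ev = fd.d > 0
    ll = np.sum(np.log(slope[ev]) - fd.lnt[ev] + eta[ev]) - np.exp(eta).sum()
    if eta0 is not None:
        ll += np.exp(eta0).sum()
    return float(ll)


def _numerical_hessian(theta: np.ndarray, fd: _FitData) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    p = theta.size
    H = np.zeros((p, p))
    for j in range(p):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _neg_loglik_grad(tp, fd)
        _, gm = _neg_loglik_grad(tm, fd)
        H[:, j] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def fit_fpm(
    cohort: Cohort,
    cause: int,
    df: int,
    fixed_beta: dict[str, float] | None = None,
    knots: SplineSpec | None = None,
    covariates: list[str] | None = None,
    max_iter: int = 500,
) -> CauseSpecificModel:
    """Maximum-likelihood fit of a cause-specific flexible parametric model.

    Parameters
    ----------
    cohort
        Follow-up data (possibly period-window sliced: left truncation is
        handled through the entry times).
    cause
        Target cause in ``1..K``; other causes' deaths are censored.
    df
        Spline degrees of freedom for the log cumulative baseline hazard.
    fixed_beta
        Coefficients to hold fixed at given values (keyed by covariate name);
        implemented as a per-subject offset so only the remaining parameters
        are estimated.  This is the recalibration device.
    knots
        Reuse a previously placed knot layout instead of placing knots from
        this cohort's event times.
    covariates
        Design columns to include; defaults to all cohort covariates.
    """
    if not 1 <= cause <= cohort.K:
        raise ValueError(f"cause {cause} outside 1..{cohort.K}")
    cov_all = list(cohort.covariates) if covariates is None else list(covariates)
    fixed_beta = dict(fixed_beta or {})
    unknown = set(fixed_beta) - set(cov_all)
    if unknown:
        raise ValueError(f"fixed_beta names not among covariates: {sorted(unknown)}")
    free_cov = [c for c in cov_all if c not in fixed_beta]

    data = cohort.data
    ev_mask = data["status"].to_numpy(dtype=int) == cause
    n_events = int(ev_mask.sum())
    n_free = df + 1 + len(free_cov)
    if n_events < n_free:
        raise InsufficientEventsError(
            f"cause {cause}: {n_events} events but {n_free} free parameters"
        )

    if knots is None:
        spec = place_knots(np.log(data.loc[ev_mask, "exit"].to_numpy(dtype=float)), df)
    else:
        spec = knots
        if spec.df != df:
            raise ValueError(f"supplied knots have df {spec.df}, requested {df}")

    offset = None
    if fixed_beta:
        Xf = cohort.design_matrix(list(fixed_beta))
        offset = Xf @ np.asarray([fixed_beta[c] for c in fixed_beta], dtype=float)

    fd = _FitData(cohort, cause, spec, free_cov, offset)

    # start from the matching exponential model: gamma = (ln rate, 1, 0...)
    person_time = float(np.sum(fd.t - fd.entry))
    rate = max(n_events, 0.5) / max(person_time, 1e-12)
    theta0 = np.zeros(df + 1 + len(free_cov))
    theta0[0] = np.log(rate) - (float(np.mean(fd.offset)) if offset is not None else 0.0)
    theta0[1] = 1.0

    res = optimize.minimize(
        _neg_loglik_grad, theta0, args=(fd,), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
    )
    _, g = _neg_loglik_grad(res.x, fd)
    gnorm = float(np.max(np.abs(g)))
    # relative tolerance: gradient noise scales with the number of subjects
    gtol = 1e-5 * max(1.0, n_events)
    if gnorm > gtol:
        # Nelder-Mead restart from the last iterate, then quasi-Newton polish
        nm = optimize.minimize(
            lambda th: _neg_loglik_grad(th, fd)[0], res.x,
            method="Nelder-Mead", options={"maxiter": 2000, "fatol": 1e-12},
        )
        res = optimize.minimize(
            _neg_loglik_grad, nm.x, args=(fd,), jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
        )
        _, g = _neg_loglik_grad(res.x, fd)
        gnorm = float(np.max(np.abs(g)))
        if gnorm > 10 * gtol:
            raise ConvergenceError(
                f"optimizer failed for cause {cause}: |grad|_max = {gnorm:.3g}",
                last_params=res.x, grad_norm=gnorm,
            )

    theta = res.x
    gamma = theta[: df + 1]
    beta_free = theta[df + 1:]

    # covariance of free parameters from the inverse observed information
    H = _numerical_hessian(theta, fd)
    try:
        cov_free = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_free = np.full((theta.size, theta.size), np.nan)

    # assemble beta in the original covariate order, fixed values interleaved
    beta = np.zeros(len(cov_all))
    constrained = np.zeros(len(cov_all), dtype=bool)
    se = np.full(len(cov_all), np.nan)
    free_idx = {c: i for i, c in enumerate(free_cov)}
    diag = np.diag(cov_free)
    for i, c in enumerate(cov_all):
        if c in fixed_beta:
            beta[i] = fixed_beta[c]
            constrained[i] = True
        else:
            j = df + 1 + free_idx[c]
            beta[i] = beta_free[free_idx[c]]
            se[i] = np.sqrt(diag[j]) if diag[j] > 0 else np.nan

    # monotonicity audit of H(t) on a grid spanning the observed times
    grid = np.exp(np.linspace(spec.knots[0], spec.knots[-1], 200))
    slope_grid = rcs_deriv(spec, np.log(grid)) @ gamma[1:]
    monotone = bool(np.all(slope_grid > 0))

    model = CauseSpecificModel(
        cause=cause, spline=spec, gamma=gamma,
        beta_names=cov_all, beta=beta, constrained=constrained,
        fit_info={
            "loglik": float(-res.fun),
            "converged": True,
            "grad_max_norm": gnorm,
            "n_events": n_events,
            "n_subjects": len(data),
            "monotone": monotone,
            "beta_se": {c: (None if np.isnan(s) else float(s))
                        for c, s in zip(cov_all, se)},
            "cov_free": cov_free,
            "free_params": ["gamma%d" % i for i in range(df + 1)] + free_cov,
        },
    )
    return model


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def _bx(model: CauseSpecificModel, x) -> float:
    if x is None:
        return 0.0
    if isinstance(x, dict):
        extra = set(x) - set(model.beta_names)
        if extra:
            raise ValueError(f"unknown covariates {sorted(extra)}")
        return float(sum(model.beta_dict()[k] * v for k, v in x.items()))
    arr = np.asarray(x, dtype=float)
    if arr.size != len(model.beta_names):
        raise ValueError("covariate vector length mismatch")
    return float(model.beta @ arr)


def cumulative_hazard(model: CauseSpecificModel, t, x=None):
    """H_k(t|x) = exp(s(ln t) + beta'x); 0 at t = 0."""
    bx = _bx(model, x)
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tt < 0):
        raise ValueError("time must be >= 0")
    out = np.zeros_like(tt)
    pos = tt > 0
    if pos.any():
        B = rcs_eval(model.spline, np.log(tt[pos]))
        out[pos] = np.exp(model.gamma[0] + B @ model.gamma[1:] + bx)
    return out[0] if np.ndim(t) == 0 else out


def survival(model: CauseSpecificModel, t, x=None):
    """Cause-specific survival S_k(t|x) = exp(-H_k(t|x))."""
    return np.exp(-cumulative_hazard(model, t, x))


def hazard(model: CauseSpecificModel, t, x=None):
    """Cause-specific hazard h_k(t|x) = H_k(t|x) * s'(ln t) / t."""
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tt <= 0):
        raise ValueError("hazard requires t > 0")
    bx = _bx(model, x)
    lnt = np.log(tt)
    B = rcs_eval(model.spline, lnt)
    Bd = rcs_deriv(model.spline, lnt)
    H = np.exp(model.gamma[0] + B @ model.gamma[1:] + bx)
    slope = Bd @ model.gamma[1:]
    out = H * slope / tt
    return out[0] if np.ndim(t) == 0 else out
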