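"""Calibration and discrimination of competing-risks risk predictions.

Calibration-in-the-large compares the cohort-average predicted CIF with the
Aalen-Johansen estimate (and the all-cause predicted risk with 1 - KM) at a
horizon, with percentile bootstrap intervals.  Calibration curves smooth
jackknife pseudo-values as a function of the predicted risk with a symmetric
nearest-neighbour local mean; the integrated calibration index (ICI) is the
mean absolute gap between the smoothed observed risk and the predicted risk
across subjects.  Discrimination uses a Wolbers-style concordance index that
orders subjects by their predicted CIF for the cause of interest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort
from .fpm import CompetingRisksModel
from .nonparametric import PseudoValueSet, aalen_johansen, pseudo_values
from .prediction import marginal_cif, predict_cif, restricted_life_years_lost

__all__ = [
    "CalibrationReport",
    "CalibrationCurve",
    "calibration_in_the_large",
    "calibration_curve",
    "ici",
    "cif_concordance",
    "assess_calibration",
    "plot_calibration",
]

# internal quadrature grid density for horizon predictions
_N_PANELS = 32


def _horizon_grid(t: float) -> np.ndarray:
    return np.linspace(t / _N_PANELS, t, _N_PANELS)


def calibration_in_the_large(
    model: CompetingRisksModel,
    validation_cohort: Cohort,
    t: float,
    B: int = 500,
    seed: int | None = None,
    nodes: int = 30,
) -> dict:
    """Predicted-minus-observed marginal risk at horizon ``t``.

    Returns ``{cause: {...}, "all": {...}}`` where each entry carries the
    marginal predicted risk, the nonparametric observed risk, their
    difference, and (for ``B > 0``) a 95% percentile bootstrap interval over
    resamples of the validation cohort in which both terms are recomputed.
    """
    K = model.K
    pred = predict_cif(model, validation_cohort, _horizon_grid(t), nodes=nodes)
    cif_t, cif_all_t, _ = pred.at(t)          # (K, N), (N,)
    obs = aalen_johansen(validation_cohort)
    observed = np.array([obs.cif_at(k, t) for k in range(1, K + 1)])
    observed_all = obs.all_cause_risk_at(t)

    out = {}
    for k in range(1, K + 1):
        out[k] = {
            "predicted": float(cif_t[k - 1].mean()),
            "observed": float(observed[k - 1]),
            "difference": float(cif_t[k - 1].mean() - observed[k - 1]),
        }
    out["all"] = {
        "predicted": float(cif_all_t.mean()),
        "observed": float(observed_all),
        "difference": float(cif_all_t.mean() - observed_all),
    }

    if B and B > 0:
        if B < 50:
            import warnings
            warnings.warn(f"B = {B} bootstrap resamples is small; intervals unstable")
        rng = np.random.default_rng(seed)
        n = len(validation_cohort)
        diffs = np.empty((B, K + 1))
        for b in range(B):
            idx = rng.integers(0, n, n)
            sub = validation_cohort.subset(idx)
            obs_b = aalen_johansen(sub)
            for k in range(1, K + 1):
                diffs[b, k - 1] = cif_t[k - 1, idx].mean() - obs_b.cif_at(k, t)
            diffs[b, K] = cif_all_t[idx].mean() - obs_b.all_cause_risk_at(t)
        lo, hi = np.percentile(diffs, [2.5, 97.5], axis=0)
        for k in range(1, K + 1):
            out[k]["ci"] = [float(lo[k - 1]), float(hi[k - 1])]
        out["all"]["ci"] = [float(lo[K]), float(hi[K])]
    return out


@dataclass
class CalibrationCurve:
    """Smoothed observed risk as a function of predicted risk.

    ``observed[i]`` is the nearest-neighbour local mean of the pseudo-values
    evaluated at subject i's predicted risk; values are kept unclipped so the
    ICI is unaffected by plotting conventions.
    """

    predicted: np.ndarray
    observed: np.ndarray
    span: float

    def sorted_points(self):
        order = np.argsort(self.predicted, kind="stable")
        return self.predicted[order], self.observed[order]


def calibration_curve(predicted, pseudo, span: float = 0.3) -> CalibrationCurve:
    """Nearest-neighbour local-mean calibration curve.

    For each subject, the ``span`` fraction of subjects nearest in
    predicted-risk rank (a symmetric window, truncated at the edges) is
    averaged over their pseudo-values.  Pseudo-values outside [0, 1] are used
    as-is: clipping before averaging would bias the local means.
    """
    pred = np.asarray(predicted, dtype=float)
    pv = pseudo.values if isinstance(pseudo, PseudoValueSet) else np.asarray(pseudo, float)
    if pred.shape != pv.shape:
        raise ValueError("predicted and pseudo-value vectors differ in length")
    n = pred.size
    if n < 20:
        raise ValueError(f"only {n} subjects: nearest-neighbour smoother is unstable")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if np.any(pred < 0) or np.any(pred > 1):
        raise ValueError("predicted risks must lie in [0, 1]")

    k = max(3, int(round(span * n)))
    k = min(k + (1 - k % 2), n)        # odd window for rank symmetry
    order = np.argsort(pred, kind="stable")
    pv_sorted = pv[order]
    csum = np.concatenate([[0.0], np.cumsum(pv_sorted)])
    half = k // 2
    ranks = np.arange(n)
    lo = np.clip(ranks - half, 0, n - k)
    hi = lo + k
    smoothed_sorted = (csum[hi] - csum[lo]) / k
    observed = np.empty(n)
    observed[order] = smoothed_sorted
    return CalibrationCurve(predicted=pred, observed=observed, span=span)


def ici(predicted, curve) -> float:
    """Integrated calibration index: mean |smoothed observed - predicted|."""
    pred = np.asarray(predicted, dtype=float)
    obs = curve.observed if isinstance(curve, CalibrationCurve) else np.asarray(curve, float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and curve vectors differ in length")
    return float(np.mean(np.abs(obs - pred)))


def cif_concordance(model: CompetingRisksModel, validation_cohort: Cohort,
                    cause: int, tau: float, nodes: int = 30) -> float:
    """Concordance of predicted CIF orderings with observed cause-k outcomes.

    A pair (i, j) is comparable when i dies from ``cause`` at t_i < min(t_j,
    tau) and j is either still event-free at t_i or has already had a
    competing event.  The pair is concordant when i's predicted F_k(tau|x) is
    the larger; prediction ties score 1/2.  No censoring weights are applied
    (naive comparable-pairs version).
    """
    d = validation_cohort.data
    exit_ = d["exit"].to_numpy(dtype=float)
    status = d["status"].to_numpy(dtype=int)
    if tau > exit_.max():
        raise ValueError(f"tau {tau} beyond max follow-up {exit_.max()}")
    pred = predict_cif(model, validation_cohort, _horizon_grid(tau), nodes=nodes)
    f = pred.at(tau)[0][cause - 1]     # (N,)

    is_case = (status == cause) & (exit_ < tau)
    competing = (status != 0) & (status != cause)
    # comparable[i, j]: i a case, and j later or a prior competing event
    later = exit_[None, :] > exit_[:, None]
    comp = is_case[:, None] & (later | competing[None, :])
    np.fill_diagonal(comp, False)
    n_comp = comp.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs at this horizon")
    gt = f[:, None] > f[None, :]
    eq = f[:, None] == f[None, :]
    score = (comp & gt).sum() + 0.5 * (comp & eq).sum()
    return float(score / n_comp)


@dataclass
class CalibrationReport:
    """Bundle of calibration and discrimination results at one horizon."""

    horizon: float
    cal_large: dict
    ici: dict = field(default_factory=dict)          # target -> ICI value
    rlyl_predicted: dict = field(default_factory=dict)
    rlyl_observed: dict = field(default_factory=dict)
    concordance: dict = field(default_factory=dict)  # cause -> c-index
    curves: dict = field(default_factory=dict)       # target -> CalibrationCurve

    def to_dict(self) -> dict:
        def _key(k):
            return str(k)
        return {
            "horizon": self.horizon,
            "calibration_in_the_large": {_key(k): v for k, v in self.cal_large.items()},
            "ici": {_key(k): v for k, v in self.ici.items()},
            "rlyl_predicted": {_key(k): v for k, v in self.rlyl_predicted.items()},
            "rlyl_observed": {_key(k): v for k, v in self.rlyl_observed.items()},
            "concordance": {_key(k): v for k, v in self.concordance.items()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def assess_calibration(
    model: CompetingRisksModel,
    validation_cohort: Cohort,
    horizon: float,
    B: int = 500,
    seed: int | None = None,
    span: float = 0.3,
    with_concordance: bool = True,
    nodes: int = 30,
) -> CalibrationReport:
    """Run the full calibration battery at one horizon.

    Computes calibration-in-the-large (with bootstrap intervals when
    ``B > 0``), pseudo-value calibration curves and the ICI for each cause and
    for the all-cause risk, predicted and observed restricted life years lost,
    and the CIF concordance per cause.
    """
    K = model.K
    cal = calibration_in_the_large(model, validation_cohort, horizon,
                                   B=B, seed=seed, nodes=nodes)
    grid = np.linspace(horizon / 200, horizon, 200)
    marg = marginal_cif(model, validation_cohort, grid, nodes=nodes)
    rlyl_pred = restricted_life_years_lost(marg, horizon)
    obs = aalen_johansen(validation_cohort)
    rlyl_obs = restricted_life_years_lost(obs, horizon)

    pred = predict_cif(model, validation_cohort, _horizon_grid(horizon), nodes=nodes)
    cif_t, cif_all_t, _ = pred.at(horizon)

    icis, curves = {}, {}
    for k in range(1, K + 1):
        pv = pseudo_values(validation_cohort, horizon, ("cause", k))
        curve = calibration_curve(cif_t[k - 1], pv, span=span)
        curves[k] = curve
        icis[k] = ici(cif_t[k - 1], curve)
    pv_all = pseudo_values(validation_cohort, horizon, "all_cause")
    curve_all = calibration_curve(cif_all_t, pv_all, span=span)
    curves["all"] = curve_all
    icis["all"] = ici(cif_all_t, curve_all)

    conc = {}
    if with_concordance:
        for k in range(1, K + 1):
            conc[k] = cif_concordance(model, validation_cohort, k, horizon, nodes=nodes)

    return CalibrationReport(
        horizon=float(horizon), cal_large=cal, ici=icis,
        rlyl_predicted=rlyl_pred, rlyl_observed=rlyl_obs,
        concordance=conc, curves=curves,
    )


def plot_calibration(report: CalibrationReport, path=None):
    """Calibration plot panels (one per cause plus all-cause)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    targets = [t for t in report.curves]
    fig, axes = plt.subplots(1, len(targets), figsize=(4 * len(targets), 4),
                             squeeze=False)
    for ax, tgt in zip(axes[0], targets):
        curve = report.curves[tgt]
        p, o = curve.sorted_points()
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.plot(p, np.clip(o, 0, 1), "-", color="C0")
        label = f"cause {tgt}" if tgt != "all" else "all causes"
        ax.set_title(f"{label}: ICI = {report.ici[tgt]:.3f}")
        ax.set_xlabel("predicted risk")
        ax.set_ylabel("observed risk (smoothed pseudo-values)")
        lim = max(p.max(), np.clip(o, 0, 1).max()) * 1.05
        ax.set_xlim(0, lim)
        ax.set_ylim(0, lim)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
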