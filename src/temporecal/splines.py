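"""Restricted cubic spline bases on the log-time axis.

The log cumulative baseline hazard of a flexible parametric survival model is
represented as a restricted cubic spline in log time.  The basis used here is
the raw truncated-power form: with knots k_1 < ... < k_m,

    v_1(x) = x
    v_j(x) = (x - k_j)^3_+ - lam_j (x - k_1)^3_+ - (1 - lam_j)(x - k_m)^3_+

for each internal knot k_j (j = 2..m-1), where lam_j = (k_m - k_j)/(k_m - k_1).
The restriction makes the basis linear beyond the boundary knots, so
extrapolation of the log cumulative hazard is linear in log time.  No
orthogonalisation is applied; the raw form keeps exported parameters easy to
interpret and re-use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplineSpec", "place_knots", "rcs_eval", "rcs_deriv"]


class DegenerateKnotsError(ValueError):
    """Raised when knot placement would produce duplicate knots."""


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout of a restricted cubic spline on the log-time scale.

    Parameters
    ----------
    knots
        Strictly increasing knot locations (log-time units).  The first and
        last entries are the boundary knots.
    """

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        if len(knots) < 2:
            raise ValueError("a spline needs at least two knots")
        if not all(np.isfinite(knots)):
            raise ValueError("knots must be finite")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise DegenerateKnotsError(f"knots must be strictly increasing: {knots}")
        object.__setattr__(self, "knots", knots)

    @property
    def df(self) -> int:
        """Number of basis terms excluding the intercept (= #knots - 1)."""
        return len(self.knots) - 1

    def to_dict(self) -> dict:
        return {"knots": list(self.knots), "df": self.df}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        spec = cls(knots=tuple(d["knots"]))
        if "df" in d and int(d["df"]) != spec.df:
            raise ValueError("inconsistent df in serialized spline spec")
        return spec


def place_knots(log_event_times: np.ndarray, df: int) -> SplineSpec:
    """Place knots for a restricted cubic spline from observed log event times.

    Boundary knots sit at the minimum and maximum of the uncensored log event
    times; the ``df - 1`` internal knots sit at equally spaced centiles
    (df = 5 puts them at the 20th/40th/60th/80th centiles).

    Raises
    ------
    DegenerateKnotsError
        If the data carry fewer distinct values than required knots.
    ValueError
        If ``df < 1`` or the times are empty or non-finite.
    """
    t = np.asarray(log_event_times, dtype=float).ravel()
    if t.size == 0:
        raise ValueError("no event times supplied for knot placement")
    if not np.all(np.isfinite(t)):
        raise ValueError("log event times must be finite")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    probs = np.linspace(0.0, 1.0, df + 1)
    knots = np.quantile(t, probs)
    if np.any(np.diff(knots) <= 0):
        raise DegenerateKnotsError(
            f"cannot place {df + 1} distinct knots: centiles collapse to {knots}"
        )
    return SplineSpec(knots=tuple(knots))


def _as_array(x) -> tuple[np.ndarray, bool]:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError("spline argument must be finite")
    return arr, np.ndim(x) == 0


def rcs_eval(spec: SplineSpec, x) -> np.ndarray:
    """Evaluate the restricted cubic basis at ``x``.

    Returns an array of shape ``(df,)`` for scalar ``x`` or ``(n, df)`` for a
    vector, excluding the intercept column (the model carries the intercept).
    """
    arr, scalar = _as_array(x)
    k = np.asarray(spec.knots)
    kmin, kmax = k[0], k[-1]
    cols = [arr]
    for kj in k[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        term = (
            np.clip(arr - kj, 0.0, None) ** 3
            - lam * np.clip(arr - kmin, 0.0, None) ** 3
            - (1.0 - lam) * np.clip(arr - kmax, 0.0, None) ** 3
        )
        cols.append(term)
    out = np.column_stack(cols)
    return out[0] if scalar else out


def rcs_deriv(spec: SplineSpec, x) -> np.ndarray:
    """First derivative of :func:`rcs_eval` with respect to its argument."""
    arr, scalar = _as_array(x)
    k = np.asarray(spec.knots)
    kmin, kmax = k[0], k[-1]
    cols = [np.ones_like(arr)]
    for kj in k[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        term = 3.0 * (
            np.clip(arr - kj, 0.0, None) ** 2
            - lam * np.clip(arr - kmin, 0.0, None) ** 2
            - (1.0 - lam) * np.clip(arr - kmax, 0.0, None) ** 2
        )
        cols.append(term)
    out = np.column_stack(cols)
    return out[0] if scalar else out
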