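"""Registry-style competing-risks follow-up data and period-window slicing.

Follow-up is recorded on the analysis time scale (years since diagnosis);
calendar position is recovered as ``dx_year + t``.  A period window restricts
the analysis to follow-up accrued inside a recent calendar interval: subjects
diagnosed before the window enter late (delayed entry / left truncation) and
follow-up extending past the window is administratively censored.  This is the
classical period-analysis device for keeping hazard estimates up to date when
survival improves over calendar time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .splines import SplineSpec, place_knots, rcs_eval

__all__ = [
    "Cohort",
    "PeriodWindow",
    "CohortValidationError",
    "read_cohort",
    "apply_period_window",
]

#: reserved (non-covariate) column names in the cohort frame
CORE_COLUMNS = ("id", "entry", "exit", "status", "dx_year")


class CohortValidationError(ValueError):
    """Input rows violate the follow-up invariants; carries a row report."""

    def __init__(self, report: pd.DataFrame):
        self.report = report
        lines = "; ".join(
            f"row {int(r.row)}: {r.reason}" for r in report.itertuples()
        )
        super().__init__(f"invalid cohort rows — {lines}")


@dataclass(frozen=True)
class PeriodWindow:
    """Half-open calendar interval [start, end) in decimal years."""

    start: float
    end: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"window start must precede end: [{self.start}, {self.end})")


@dataclass
class Cohort:
    """Subject-level competing-risks follow-up.

    Attributes
    ----------
    data
        One row per subject: ``id``, ``entry``, ``exit`` (years since
        diagnosis), ``status`` (0 censored, k = death from cause k),
        ``dx_year`` (decimal calendar year of diagnosis) plus one numeric
        design column per covariate.
    K
        Number of competing causes.
    covariates
        Names of the design columns, in model order.
    schema
        Optional description of how raw covariates were expanded into design
        columns (categorical reference levels, spline knots for non-linear
        continuous effects); carried so a model fitted here can be applied to
        a new dataset with the same expansion.
    """

    data: pd.DataFrame
    K: int
    covariates: list[str] = field(default_factory=list)
    schema: dict | None = None

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        missing = [c for c in CORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort frame missing columns: {missing}")
        missing_cov = [c for c in self.covariates if c not in self.data.columns]
        if missing_cov:
            raise ValueError(f"cohort frame missing covariate columns: {missing_cov}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    def design_matrix(self, columns: list[str] | None = None) -> np.ndarray:
        cols = self.covariates if columns is None else columns
        if not cols:
            return np.zeros((len(self.data), 0))
        return self.data[cols].to_numpy(dtype=float)

    def event_counts(self) -> dict[int, int]:
        counts = self.data["status"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in range(self.K + 1)}

    def subset(self, mask) -> "Cohort":
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def validate_rows(df: pd.DataFrame, K: int) -> pd.DataFrame:
    """Return a row-indexed report of invariant violations (empty if clean)."""
    problems = []
    entry = df["entry"].to_numpy(dtype=float)
    exit_ = df["exit"].to_numpy(dtype=float)
    status = df["status"].to_numpy()
    for i in range(len(df)):
        if not np.isfinite(entry[i]) or entry[i] < 0:
            problems.append((i, f"entry time {entry[i]} invalid"))
        elif not np.isfinite(exit_[i]) or exit_[i] <= entry[i]:
            problems.append((i, f"exit {exit_[i]} not after entry {entry[i]}"))
        s = status[i]
        if not (float(s).is_integer() and 0 <= int(s) <= K):
            problems.append((i, f"status {s} not in 0..{K}"))
    return pd.DataFrame(problems, columns=["row", "reason"])


def _expand_covariates(df: pd.DataFrame, schema: dict) -> tuple[pd.DataFrame, list[str], dict]:
    """Expand raw covariate columns into numeric design columns.

    Categorical covariates become indicator columns against a declared
    reference level; continuous covariates are taken as-is or expanded with a
    restricted cubic spline basis when ``spline_df > 1``.  Knots computed here
    are written back into the returned schema so the same expansion can be
    replayed on a validation dataset.
    """
    out = {}
    names: list[str] = []
    resolved = {"covariates": []}
    for cov in schema.get("covariates", []):
        name = cov["name"]
        if name not in df.columns:
            raise ValueError(f"covariate column '{name}' not in CSV")
        kind = cov.get("type", "continuous")
        entry = dict(cov)
        if kind == "categorical":
            raw = df[name].astype(str)
            levels = [str(l) for l in cov.get("levels", sorted(raw.unique()))]
            ref = str(cov.get("reference", levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level '{ref}' not among levels of '{name}'")
            unknown = set(raw.unique()) - set(levels)
            if unknown:
                raise ValueError(f"unknown levels {sorted(unknown)} in covariate '{name}'")
            for lev in levels:
                if lev == ref:
                    continue
                col = f"{name}_{lev}"
                out[col] = (raw == lev).astype(float)
                names.append(col)
            entry.update(levels=levels, reference=ref)
        elif kind == "continuous":
            vals = df[name].to_numpy(dtype=float)
            sdf = int(cov.get("spline_df", 1))
            if sdf <= 1:
                out[name] = vals
                names.append(name)
            else:
                if "knots" in cov:
                    spec = SplineSpec(knots=tuple(cov["knots"]))
                else:
                    spec = place_knots(vals, sdf)
                basis = rcs_eval(spec, vals)
                for j in range(basis.shape[1]):
                    col = f"{name}_s{j + 1}"
                    out[col] = basis[:, j]
                    names.append(col)
                entry["knots"] = list(spec.knots)
        else:
            raise ValueError(f"unknown covariate type '{kind}' for '{name}'")
        resolved["covariates"].append(entry)
    return pd.DataFrame(out, index=df.index), names, resolved


def read_cohort(path, schema: dict) -> Cohort:
    """Read a subject-level CSV into a validated :class:`Cohort`.

    ``schema`` declares ``K`` and the covariate expansion, e.g.::

        {"K": 2,
         "covariates": [
             {"name": "stage", "type": "categorical", "reference": "1"},
             {"name": "age", "type": "continuous", "spline_df": 3},
         ]}

    Lines starting with ``#`` are treated as provenance comments.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV {path} missing required columns: {missing}")
    K = int(schema["K"])
    report = validate_rows(df, K)
    if len(report):
        raise CohortValidationError(report)
    design, names, resolved = _expand_covariates(df, schema)
    core = df[list(CORE_COLUMNS)].copy()
    core["status"] = core["status"].astype(int)
    data = pd.concat([core, design], axis=1)
    resolved["K"] = K
    return Cohort(data=data, K=K, covariates=names, schema=resolved)


def apply_period_window(cohort: Cohort, window: PeriodWindow) -> Cohort:
    """Restrict follow-up to a calendar period window using delayed entry.

    Per subject, follow-up time t sits at calendar position ``dx_year + t``.
    The new entry time is ``max(entry, start - dx_year)`` and the new exit is
    ``min(exit, end - dx_year)``; an event falling at or beyond the window end
    is recoded as censored at the truncation point (half-open convention), and
    subjects with no follow-up inside the window are dropped.  The returned
    cohort carries a ``diagnosed_in_window`` flag: such subjects are at risk
    from time zero and are the only ones informing early-time hazards.
    """
    df = cohort.data.copy()
    dx = df["dx_year"].to_numpy(dtype=float)
    entry = df["entry"].to_numpy(dtype=float)
    exit_ = df["exit"].to_numpy(dtype=float)
    status = df["status"].to_numpy(dtype=int)

    new_entry = np.maximum(entry, window.start - dx)
    new_exit = np.minimum(exit_, window.end - dx)
    # event at/after the window end falls outside [start, end): censor there
    censored = exit_ >= window.end - dx
    new_status = np.where(censored, 0, status)
    keep = new_exit > new_entry

    df["entry"] = new_entry
    df["exit"] = new_exit
    df["status"] = new_status
    df["diagnosed_in_window"] = (dx >= window.start) & (dx < window.end)
    out = replace(cohort, data=df.loc[keep].reset_index(drop=True))
    return out
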