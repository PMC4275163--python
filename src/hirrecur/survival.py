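"""Recurrence-free survival machinery.

Kaplan-Meier estimation, log-rank tests and Cox proportional-hazards
models (via ``lifelines``), plus recurrence-window subsetting: early
windows censor events beyond the cutoff, late windows are landmark
analyses (patients must be event-free and under observation at the
cutoff, entering the risk set there with the clock kept at surgery).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from hirrecur.io_preprocess import CohortClinical

__all__ = [
    "RecurrenceWindow",
    "SurvivalFit",
    "km_estimate",
    "logrank",
    "cox_fit",
    "window_subset",
    "table2_encoding",
]


@dataclass(frozen=True)
class RecurrenceWindow:
    """Named analysis window over follow-up time (months).

    ``lo`` is a landmark (exclusive) entry bound; ``hi`` an inclusive
    censoring bound; ``None`` means unbounded.
    """

    kind: str
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.lo is not None and self.lo <= 0:
            raise ValueError("window lower bound must be > 0")
        if self.hi is not None and self.hi <= 0:
            raise ValueError("window upper bound must be > 0")
        if self.lo is not None and self.hi is not None and self.lo >= self.hi:
            raise ValueError("window bounds out of order")

    @classmethod
    def overall(cls) -> "RecurrenceWindow":
        return cls("overall")

    @classmethod
    def early(cls, tau: float = 24.0) -> "RecurrenceWindow":
        return cls("early", hi=tau)

    @classmethod
    def late(cls, tau: float = 24.0) -> "RecurrenceWindow":
        return cls("late", lo=tau)

    @classmethod
    def very_early(cls) -> "RecurrenceWindow":
        return cls("very_early", hi=12.0)

    @classmethod
    def intermediate(cls) -> "RecurrenceWindow":
        return cls("intermediate", lo=12.0, hi=24.0)


@dataclass
class SurvivalFit:
    """Cox fit summary: hazard ratios, Wald 95% CIs and p-values per term."""

    summary: pd.DataFrame  # index=term; columns hr, ci_lo, ci_hi, p
    n_used: int
    events_used: int

    def hr(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.summary.loc[term]
        return float(row["ci_lo"]), float(row["ci_hi"])

    def p(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])


def _as_arrays(times, events, groups=None):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape:
        raise ValueError("times and events must be aligned")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    if groups is None:
        return t, e, None
    g = np.asarray(groups, dtype=object)
    if g.shape != t.shape:
        raise ValueError("groups must be aligned with times")
    return t, e, g


def km_estimate(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str] | None = None,
) -> tuple[dict[str, pd.DataFrame], float]:
    """Product-limit survival curves per group plus median follow-up.

    Each curve is a step-function DataFrame (time, survival, at_risk,
    censored).  Median follow-up uses the reverse Kaplan-Meier
    convention (censoring distribution median).
    """
    t, e, g = _as_arrays(times, events, groups)
    if g is None:
        g = np.array(["all"] * len(t), dtype=object)
    curves: dict[str, pd.DataFrame] = {}
    for label in sorted(set(map(str, g))):
        mask = g == label
        if mask.sum() == 0:
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        tbl = kmf.event_table
        df = pd.DataFrame(
            {
                "time": tbl.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
                "at_risk": tbl["at_risk"].to_numpy(),
                "censored": tbl["censored"].to_numpy(),
            }
        )
        curves[label] = df
    rkmf = KaplanMeierFitter()
    rkmf.fit(t, 1 - e)
    median_followup = float(rkmf.median_survival_time_)
    return curves, median_followup


def logrank(
    times: Sequence[float], events: Sequence[int], groups: Sequence[str]
) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi2, two-sided p)."""
    t, e, g = _as_arrays(times, events, groups)
    labels = sorted(set(map(str, g)))
    if len(labels) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    for label in labels:
        if t[g == label].sum() <= 0:
            raise ValueError(f"group {label!r} has zero at-risk time")
    res = multivariate_logrank_test(t, g.astype(str), e)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    clinical: CohortClinical | pd.DataFrame,
    covariates: Sequence[str],
    entry_col: str | None = None,
) -> SurvivalFit:
    """Cox proportional-hazards fit of recurrence-free survival.

    ``covariates`` name numeric columns of the clinical table; rows with
    a missing covariate value are excluded (Table-style handling of
    unavailable staging).  If the table carries an ``entry`` column — as
    produced by :func:`window_subset` for landmark windows — it is used
    as delayed entry unless ``entry_col`` overrides it.  Ties are
    handled by Efron's method (lifelines default).
    """
    df = clinical.data if isinstance(clinical, CohortClinical) else clinical
    if entry_col is None and "entry" in df.columns:
        entry_col = "entry"
    cols = ["time_months", "event", *covariates]
    if entry_col:
        cols.append(entry_col)
    sub = df[cols].dropna(subset=list(covariates)).copy()
    for c in covariates:
        sub[c] = pd.to_numeric(sub[c])
    if int(sub["event"].sum()) < 1:
        raise ValueError("no events in analysis set")
    cph = CoxPHFitter()
    try:
        cph.fit(
            sub,
            duration_col="time_months",
            event_col="event",
            entry_col=entry_col,
        )
    except Exception as exc:  # convergence / separation diagnostics
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "hr": s["exp(coef)"],
            "ci_lo": s["exp(coef) lower 95%"],
            "ci_hi": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return SurvivalFit(summary=summary, n_used=len(sub), events_used=int(sub["event"].sum()))


def window_subset(clinical: CohortClinical, window: RecurrenceWindow) -> CohortClinical:
    """Restrict a cohort to one recurrence window.

    Early-type windows (``hi`` only) keep everyone but administratively
    censor at ``hi``.  Late/landmark windows (``lo`` set) keep only
    patients event-free and under observation beyond ``lo`` and add an
    ``entry`` column at ``lo``; time stays on the from-surgery clock.
    """
    df = clinical.data.copy()
    if window.lo is not None:
        at_risk = df["time_months"] > window.lo
        df = df.loc[at_risk].copy()
        df["entry"] = float(window.lo)
    if window.hi is not None:
        beyond = df["time_months"] > window.hi
        df.loc[beyond, "event"] = 0
        df.loc[beyond, "time_months"] = float(window.hi)
    return CohortClinical(df)


def table2_encoding(clinical: CohortClinical) -> pd.DataFrame:
    """Numeric covariate codings for Cox models.

    Dichotomies: male sex, age > 60 y, AFP > 300 ng/ml, tumor > 5 cm,
    BCLC stage B/C vs 0/A (NaN where stage unavailable); the remaining
    covariates are already 0/1.
    """
    df = clinical.data
    out = pd.DataFrame(index=df.index)
    if "sex" in df:
        out["sex_male"] = (df["sex"].astype(str) == "M").astype(int)
    if "age" in df:
        out["age_gt_60"] = (pd.to_numeric(df["age"]) > 60).astype(int)
    for col in ("afp_gt_300", "hbv", "cirrhosis", "tumor_gt_5cm", "multinodular", "vascular_invasion"):
        if col in df:
            out[col] = pd.to_numeric(df[col]).astype(int)
    if "bclc" in df:
        stage = df["bclc"].astype("string")
        out["bclc_bc"] = stage.map(lambda s: np.nan if pd.isna(s) else float(s in ("B", "C")))
    return out
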