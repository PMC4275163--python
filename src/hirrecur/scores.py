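"""Weighted-score risk classifiers and predictor integration.

Covers three things: a generic weighted gene score applied to centered
expression (e.g. a Cox-score-weighted reference classifier or an
externally supplied risk score), reference-threshold dichotomization
into high/low groups, the three-way integration of two predictors, and
a Cramer's V concordance measure on 2x2 tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from hirrecur.io_preprocess import ExpressionMatrix

__all__ = [
    "RiskScoreModel",
    "RiskCall",
    "ConcordanceResult",
    "weighted_score",
    "classify_by_thresholds",
    "integrate_predictors",
    "concordance",
]

log = logging.getLogger(__name__)

HIGH, LOW, INDET = "high", "low", "indeterminate"
HIR_HIGH, QT_LOW, INTERMEDIATE = "HIR-high", "QT-low", "intermediate"


@dataclass
class RiskScoreModel:
    """Symbol-keyed gene weights plus reference-group thresholds.

    ``high_threshold`` is the lowest score observed in the reference
    poor-prognosis group, ``low_threshold`` the highest score in the
    reference good-prognosis group: scores above the former are called
    high risk, below the latter low risk.
    """

    name: str
    gene_weights: dict[str, float]
    high_threshold: float | None = None
    low_threshold: float | None = None

    def __post_init__(self) -> None:
        if (
            self.high_threshold is not None
            and self.low_threshold is not None
            and self.low_threshold > self.high_threshold
        ):
            raise ValueError("low_threshold must not exceed high_threshold")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "name": self.name,
                    "gene_weights": self.gene_weights,
                    "high_threshold": self.high_threshold,
                    "low_threshold": self.low_threshold,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskScoreModel":
        d = json.loads(Path(path).read_text())
        return cls(
            name=d["name"],
            gene_weights={str(k): float(v) for k, v in d["gene_weights"].items()},
            high_threshold=d.get("high_threshold"),
            low_threshold=d.get("low_threshold"),
        )


@dataclass(frozen=True)
class RiskCall:
    patient_id: str
    score: float
    group: str


def weighted_score(
    model: RiskScoreModel, m: ExpressionMatrix
) -> tuple[pd.Series, list[str]]:
    """Per-sample score ``sum_g w_g x_g`` over weight genes present.

    Expression should be centered per cohort.  Returns the score series
    and the list of absent weight genes.
    """
    sym_to_row = {str(s): i for i, s in enumerate(m.gene_symbols)}
    rows, w = [], []
    absent = []
    for sym, weight in model.gene_weights.items():
        r = sym_to_row.get(sym)
        if r is None:
            absent.append(sym)
        else:
            rows.append(r)
            w.append(weight)
    if not rows:
        raise ValueError(f"no genes of score {model.name!r} present in matrix")
    scores = np.asarray(w) @ m.values[np.array(rows), :]
    return pd.Series(scores, index=m.sample_ids, name=model.name), absent


def classify_by_thresholds(
    model: RiskScoreModel, scores: pd.Series, strict: bool = True
) -> pd.DataFrame:
    """Dichotomize scores against the reference thresholds.

    Strict mode leaves scores falling between the two thresholds
    ``indeterminate``; two-group mode (``strict=False``) resolves them
    to the nearest threshold (ties to high).
    """
    if model.high_threshold is None or model.low_threshold is None:
        raise ValueError("both thresholds must be set")
    hi, lo = model.high_threshold, model.low_threshold
    group = np.where(scores > hi, HIGH, np.where(scores < lo, LOW, INDET))
    if not strict:
        gap = group == INDET
        nearer_high = np.abs(scores - hi) <= np.abs(scores - lo)
        group = np.where(gap & nearer_high, HIGH, np.where(gap, LOW, group))
    return pd.DataFrame({"score": scores, "group": group}, index=scores.index)


def integrate_predictors(
    hir_labels: Mapping[str, str] | pd.Series, risk_groups: Mapping[str, str] | pd.Series
) -> pd.Series:
    """Combine subgroup and risk calls into three strata.

    (HIR, high) -> HIR-high; (QT, low) -> QT-low; the two mixed cells ->
    intermediate.  Patients missing either call are excluded and logged.
    """
    hir = pd.Series(hir_labels)
    risk = pd.Series(risk_groups)
    common = hir.index.intersection(risk.index)
    dropped = len(hir.index.union(risk.index)) - len(common)
    if dropped:
        log.warning("integrate_predictors: %d patients lack one of the calls", dropped)
    out = {}
    for pid in common:
        h, r = str(hir[pid]), str(risk[pid])
        if h not in {"HIR", "QT"} or r not in {HIGH, LOW}:
            log.warning("integrate_predictors: skipping %s with calls (%s, %s)", pid, h, r)
            continue
        if h == "HIR" and r == HIGH:
            out[pid] = HIR_HIGH
        elif h == "QT" and r == LOW:
            out[pid] = QT_LOW
        else:
            out[pid] = INTERMEDIATE
    return pd.Series(out, name="integrated_group")


@dataclass(frozen=True)
class ConcordanceResult:
    cramers_v: float
    chi2: float
    p_value: float
    fisher_p: float | None
    n: int
    continuity_correction: bool


def concordance(table: np.ndarray | Sequence[Sequence[int]], correction: bool = True) -> ConcordanceResult:
    """Cramer's V for a 2x2 contingency table.

    ``V = sqrt(chi2 / n)`` (``min(r-1, c-1) = 1``); the chi-square uses
    the Yates continuity correction by default.  Degenerate margins are
    an error.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative counts")
    n = t.sum()
    if n <= 0:
        raise ValueError("empty table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin; Cramer's V undefined")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=correction)
    v = float(np.sqrt(chi2 / n))
    fisher_p = float(stats.fisher_exact(t)[1])
    return ConcordanceResult(
        cramers_v=v,
        chi2=float(chi2),
        p_value=float(p),
        fisher_p=fisher_p,
        n=int(n),
        continuity_correction=correction,
    )
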