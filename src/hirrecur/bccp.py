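"""Bayesian compound covariate predictor.

A single compound covariate per sample — the t-statistic-weighted sum of
signature-gene expression — is modeled with Gaussian class-conditional
densities (pooled variance) and turned into a posterior class
probability.  Samples with posterior above the threshold are called HIR,
otherwise QT.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import log_expit

from hirrecur.io_preprocess import ExpressionMatrix
from hirrecur.signature import Signature

__all__ = [
    "BCCPModel",
    "ClassPosterior",
    "compound_covariate",
    "train_bccp",
    "posterior",
    "classify_cohort",
    "loocv",
]

HIR = "HIR"
QT = "QT"


@dataclass
class BCCPModel:
    weights: np.ndarray
    feature_order: np.ndarray  # feature IDs, aligned with weights
    symbols: np.ndarray  # gene symbols, aligned with weights
    class_means: tuple[float, float]  # (m_HIR, m_QT) of the compound covariate
    pooled_variance: float
    priors: tuple[float, float] = (0.5, 0.5)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.feature_order = np.asarray(self.feature_order, dtype=object)
        self.symbols = np.asarray(self.symbols, dtype=object)
        if self.pooled_variance <= 0:
            raise ValueError("pooled variance must be positive")
        if abs(self.priors[0] + self.priors[1] - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "feature_order": self.feature_order.tolist(),
            "symbols": self.symbols.tolist(),
            "class_means": list(self.class_means),
            "pooled_variance": self.pooled_variance,
            "priors": list(self.priors),
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BCCPModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.array(d["weights"], dtype=float),
            feature_order=np.array(d["feature_order"], dtype=object),
            symbols=np.array(d["symbols"], dtype=object),
            class_means=tuple(d["class_means"]),
            pooled_variance=float(d["pooled_variance"]),
            priors=tuple(d["priors"]),
            threshold=float(d["threshold"]),
        )


@dataclass(frozen=True)
class ClassPosterior:
    sample_id: str
    compound_covariate: float
    prob_hir: float
    label: str


def compound_covariate(weights: np.ndarray, expression_column: np.ndarray) -> float:
    """Weighted sum ``c = sum_g w_g x_g`` over aligned features."""
    w = np.asarray(weights, dtype=float)
    x = np.asarray(expression_column, dtype=float)
    if w.shape != x.shape:
        raise ValueError(f"weights ({w.shape}) and expression ({x.shape}) not aligned")
    return float(w @ x)


def _align_rows(m: ExpressionMatrix, feature_ids: Sequence[str]) -> np.ndarray:
    idx = {str(f): i for i, f in enumerate(m.feature_ids)}
    missing = [f for f in feature_ids if str(f) not in idx]
    if missing:
        raise ValueError(f"features missing from matrix: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    return np.array([idx[str(f)] for f in feature_ids], dtype=int)


def _covariates(m: ExpressionMatrix, weights: np.ndarray, rows: np.ndarray) -> np.ndarray:
    return weights @ m.values[rows, :]


def train_bccp(
    training: ExpressionMatrix,
    labels: Sequence[str],
    weights: Signature | np.ndarray,
    priors: tuple[float, float] = (0.5, 0.5),
    threshold: float = 0.5,
) -> BCCPModel:
    """Fit class-conditional Gaussians of the compound covariate.

    ``labels`` must contain both ``"HIR"`` and ``"QT"`` with at least
    two samples each.  ``weights`` is a :class:`Signature` (features
    matched by ID against the training matrix) or a weight vector
    already aligned with the training features.
    """
    labels = np.asarray([str(l) for l in labels], dtype=object)
    if labels.shape[0] != training.n_samples:
        raise ValueError("labels length does not match training samples")
    present = set(labels)
    if present != {HIR, QT}:
        raise ValueError(f"training labels must be exactly {{HIR, QT}}, got {sorted(present)}")

    if isinstance(weights, Signature):
        rows = _align_rows(training, weights.feature_ids)
        w = weights.weights
        feat = np.asarray(weights.feature_ids, dtype=object)
        syms = np.asarray(weights.symbols, dtype=object)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != training.n_features:
            raise ValueError("weight vector not aligned with training features")
        rows = np.arange(training.n_features)
        feat = training.feature_ids
        syms = training.gene_symbols

    c = _covariates(training, w, rows)
    c_hir = c[labels == HIR]
    c_qt = c[labels == QT]
    if len(c_hir) < 2 or len(c_qt) < 2:
        raise ValueError("each class needs >= 2 training samples")
    v = (c_hir.var(ddof=1) * (len(c_hir) - 1) + c_qt.var(ddof=1) * (len(c_qt) - 1)) / (
        len(c) - 2
    )
    if v <= 0:
        raise ValueError("zero pooled variance of the compound covariate")
    return BCCPModel(
        weights=w,
        feature_order=feat,
        symbols=syms,
        class_means=(float(c_hir.mean()), float(c_qt.mean())),
        pooled_variance=float(v),
        priors=priors,
        threshold=threshold,
    )


def posterior(model: BCCPModel, c: float | np.ndarray) -> np.ndarray | float:
    """Posterior probability of HIR for compound covariate value(s) ``c``.

    Computed in log space; finite for all real ``c``.
    """
    c = np.asarray(c, dtype=float)
    m1, m0 = model.class_means
    v = model.pooled_variance
    p1, p0 = model.priors
    # log-odds of HIR vs QT; Gaussian densities share variance so the
    # quadratic terms cancel into a linear function of c
    log_odds = np.log(p1 / p0) + ((c - m0) ** 2 - (c - m1) ** 2) / (2.0 * v)
    prob = np.exp(log_expit(log_odds))
    return float(prob) if prob.ndim == 0 else prob


def classify_cohort(model: BCCPModel, cohort: ExpressionMatrix) -> pd.DataFrame:
    """Classify every cohort sample; match model features by gene symbol.

    The cohort is expected to have passed through
    :func:`hirrecur.io_preprocess.match_and_center`.  Features absent
    from the cohort are dropped from the compound covariate; a warning
    is raised below 50% coverage and an error at zero coverage.
    """
    sym_to_row = {str(s): i for i, s in enumerate(cohort.gene_symbols)}
    id_to_row = {str(f): i for i, f in enumerate(cohort.feature_ids)}
    rows, kept = [], []
    for j, (fid, sym) in enumerate(zip(model.feature_order, model.symbols)):
        r = id_to_row.get(str(fid), sym_to_row.get(str(sym)))
        if r is not None:
            rows.append(r)
            kept.append(j)
    if not rows:
        raise ValueError("no model features present in cohort")
    coverage = len(rows) / len(model.feature_order)
    if coverage < 0.5:
        warnings.warn(f"classify_cohort: only {coverage:.0%} signature coverage")
    c = model.weights[kept] @ cohort.values[np.array(rows), :]
    prob = posterior(model, c)
    labels = np.where(prob > model.threshold, HIR, QT)
    return pd.DataFrame(
        {
            "compound_covariate": c,
            "prob_hir": prob,
            "label": labels,
        },
        index=pd.Index(cohort.sample_ids, name="sample_id"),
    )


def loocv(
    training: ExpressionMatrix,
    labels: Sequence[str],
    weights: Signature | np.ndarray,
    weights_recompute: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Leave-one-out cross-validation of the predictor.

    Each sample is classified by a model trained without it.  With
    ``weights_recompute`` the t-statistic weights are refit per fold
    from a two-class random-variance t-test (full honest CV); otherwise
    the supplied weights are reused.  Folds whose training half loses a
    class are skipped and reported with NaN posterior.
    """
    from hirrecur.signature import random_variance_ttest

    labels = np.asarray([str(l) for l in labels], dtype=object)
    n = training.n_samples
    if n < 3:
        raise ValueError("LOOCV needs >= 3 samples")

    records = []
    n_err = 0
    n_scored = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub = training.subset_samples(training.sample_ids[keep])
        sub_labels = labels[keep]
        if len(set(sub_labels)) < 2 or min(
            (sub_labels == HIR).sum(), (sub_labels == QT).sum()
        ) < 2:
            records.append((training.sample_ids[i], np.nan, np.nan, "skipped"))
            continue
        if weights_recompute:
            tab = random_variance_ttest(sub, sub_labels, ref=QT)  # HIR minus QT
            fold_weights: Signature | np.ndarray = tab["t_stat"].to_numpy()
            model = train_bccp(sub, sub_labels, fold_weights)
        else:
            model = train_bccp(sub, sub_labels, weights)
        if isinstance(weights, Signature) and not weights_recompute:
            rows = _align_rows(training, model.feature_order)
        else:
            rows = np.arange(training.n_features)
        c = compound_covariate(model.weights, training.values[rows, i])
        p = posterior(model, c)
        label = HIR if p > model.threshold else QT
        n_scored += 1
        n_err += int(label != labels[i])
        records.append((training.sample_ids[i], c, p, label))

    df = pd.DataFrame(
        records, columns=["sample_id", "compound_covariate", "prob_hir", "label"]
    ).set_index("sample_id")
    error_rate = n_err / n_scored if n_scored else float("nan")
    return df, error_rate
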