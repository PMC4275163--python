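"""Compact predictors derived from the full signature.

Three reduction routes: nearest-shrunken-centroid feature selection with
a cross-validated miscalculation-rate curve, category-stratified
selection of a fixed-size gene panel, and a univariate survival screen
followed by backward stepwise elimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from sklearn.model_selection import StratifiedKFold

from hirrecur.io_preprocess import CohortClinical, ExpressionMatrix
from hirrecur.scores import ConcordanceResult, concordance
from hirrecur.signature import Signature

__all__ = [
    "ShrunkenCentroidModel",
    "StepwiseResult",
    "nsc_fit",
    "nsc_predict",
    "select_by_category",
    "stepwise_select",
    "model_concordance",
]


# ---------------------------------------------------------------------------
# nearest shrunken centroids


@dataclass
class ShrunkenCentroidModel:
    """Soft-thresholded class centroids at one shrinkage level Delta.

    Standardized centroid deviations ``d_gk = (xbar_gk - xbar_g) /
    (m_k (s_g + s0))`` are soft-thresholded by Delta; the surviving
    features define the classifier.  ``cv_miscalculation_rate`` is
    filled by :func:`nsc_fit` when cross-validation is requested.
    """

    classes: list[str]
    overall_centroid: np.ndarray
    shrunken_centroids: np.ndarray  # genes x classes
    pooled_sd: np.ndarray
    s0: float
    priors: np.ndarray
    delta: float
    surviving_features: np.ndarray  # feature IDs
    feature_ids: np.ndarray
    cv_miscalculation_rate: float | None = None

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_features)


def _nsc_train(
    x: np.ndarray, y: np.ndarray, classes: list[str], delta: float, feature_ids: np.ndarray
) -> ShrunkenCentroidModel:
    n = x.shape[1]
    xbar = x.mean(axis=1)
    s2 = np.zeros(x.shape[0])
    cents = []
    ns = []
    for k in classes:
        xk = x[:, y == k]
        ns.append(xk.shape[1])
        cents.append(xk.mean(axis=1))
        s2 += ((xk - xk.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt(s2 / (n - len(classes)))
    s0 = float(np.median(s))
    cent = np.column_stack(cents)
    d = np.empty_like(cent)
    for j, nk in enumerate(ns):
        mk = np.sqrt(max(1.0 / nk - 1.0 / n, 1e-12))
        d[:, j] = (cent[:, j] - xbar) / (mk * (s + s0))
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken_cent = np.empty_like(cent)
    for j, nk in enumerate(ns):
        mk = np.sqrt(max(1.0 / nk - 1.0 / n, 1e-12))
        shrunken_cent[:, j] = xbar + mk * (s + s0) * d_shrunk[:, j]
    if delta == 0:
        surviving = np.arange(x.shape[0])
    else:
        surviving = np.flatnonzero(np.abs(d).max(axis=1) > delta)
    return ShrunkenCentroidModel(
        classes=list(classes),
        overall_centroid=xbar,
        shrunken_centroids=shrunken_cent,
        pooled_sd=s,
        s0=s0,
        priors=np.asarray(ns, dtype=float) / n,
        delta=float(delta),
        surviving_features=feature_ids[surviving],
        feature_ids=feature_ids,
    )


def nsc_predict(model: ShrunkenCentroidModel, x: np.ndarray) -> np.ndarray:
    """Classify columns of ``x`` by discriminant score.

    ``delta_k(x) = sum_g (x_g - xbar'_gk)^2 / (s_g + s0)^2 - 2 log pi_k``;
    with zero surviving features every sample falls back to the
    largest-prior class.
    """
    if model.n_surviving == 0:
        k = int(np.argmax(model.priors))
        return np.array([model.classes[k]] * x.shape[1], dtype=object)
    denom = (model.pooled_sd + model.s0) ** 2
    scores = np.empty((x.shape[1], len(model.classes)))
    for j in range(len(model.classes)):
        diff = x - model.shrunken_centroids[:, j][:, None]
        scores[:, j] = (diff**2 / denom[:, None]).sum(axis=0) - 2.0 * np.log(model.priors[j])
    return np.asarray([model.classes[j] for j in scores.argmin(axis=1)], dtype=object)


def nsc_fit(
    m: ExpressionMatrix,
    labels: Sequence[str],
    delta_grid: Sequence[float],
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[list[ShrunkenCentroidModel], pd.DataFrame]:
    """Fit shrunken-centroid models across a Delta grid with k-fold CV.

    Returns one model per Delta (with its CV miscalculation rate filled
    in) and the error curve as a DataFrame (delta, n_surviving,
    cv_error).
    """
    y = np.asarray([str(l) for l in labels], dtype=object)
    if y.shape[0] != m.n_samples:
        raise ValueError("labels not aligned with samples")
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError("expected two classes")
    for k in classes:
        if (y == k).sum() < 3:
            raise ValueError(f"class {k!r} needs >= 3 samples")
    deltas = [float(d) for d in delta_grid]
    if any(d < 0 for d in deltas):
        raise ValueError("Delta must be >= 0")

    x = m.values
    n_splits = min(cv_folds, min((y == k).sum() for k in classes))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(x.T, y))

    models = []
    curve = []
    for delta in deltas:
        model = _nsc_train(x, y, classes, delta, m.feature_ids)
        errs = 0
        total = 0
        for train_idx, test_idx in folds:
            fold_model = _nsc_train(x[:, train_idx], y[train_idx], classes, delta, m.feature_ids)
            pred = nsc_predict(fold_model, x[:, test_idx])
            errs += int((pred != y[test_idx]).sum())
            total += len(test_idx)
        model.cv_miscalculation_rate = errs / total
        models.append(model)
        curve.append((delta, model.n_surviving, model.cv_miscalculation_rate))
    curve_df = pd.DataFrame(curve, columns=["delta", "n_surviving", "cv_error"])
    return models, curve_df


# ---------------------------------------------------------------------------
# category-stratified panel selection


def select_by_category(
    signature: Signature,
    categories: Mapping[str, str],
    per_category: int = 2,
    n_categories: int = 10,
    seed: int = 0,
) -> Signature:
    """Randomly pick ``per_category`` features from each top category.

    Categories are ranked by membership size (ties broken by name);
    every selected category must have at least ``per_category`` members.
    Deterministic given ``seed``.
    """
    members: dict[str, list[str]] = {}
    for fid in signature.feature_ids:
        cat = categories.get(fid)
        if cat is not None:
            members.setdefault(str(cat), []).append(fid)
    ranked = sorted(members, key=lambda c: (-len(members[c]), c))[:n_categories]
    if len(ranked) < n_categories:
        raise ValueError(f"only {len(ranked)} categories available, need {n_categories}")
    short = [c for c in ranked if len(members[c]) < per_category]
    if short:
        raise ValueError(f"categories with < {per_category} members: {short}")
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for cat in ranked:
        chosen.extend(rng.choice(members[cat], size=per_category, replace=False))
    sub = signature.subset(chosen)
    sub.provenance["selection"] = {
        "categories": ranked,
        "per_category": per_category,
        "seed": seed,
    }
    return sub


# ---------------------------------------------------------------------------
# univariate screen + backward stepwise


@dataclass
class StepwiseResult:
    screened_features: list[str]
    selected_features: list[str]
    coefficients: dict[str, float] = field(default_factory=dict)
    screen_alpha: float = 0.005
    retain_alpha: float = 0.1
    dropped_collinear: list[str] = field(default_factory=list)


def _univariate_cox_p(time: np.ndarray, event: np.ndarray, x: np.ndarray) -> float:
    df = pd.DataFrame({"time_months": time, "event": event, "g": x})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time_months", event_col="event")
    except Exception:
        return 1.0
    return float(cph.summary.loc["g", "p"])


def _univariate_logistic_p(event: np.ndarray, x: np.ndarray) -> float:
    X = sm.add_constant(x)
    try:
        fit = sm.Logit(event, X).fit(disp=0)
    except Exception:
        return 1.0
    return float(fit.pvalues[-1])


def stepwise_select(
    m: ExpressionMatrix,
    clinical: CohortClinical,
    screen_alpha: float = 0.005,
    retain_alpha: float = 0.1,
    screen: str = "cox",
    final: str = "logistic",
) -> StepwiseResult:
    """Univariate screen then backward elimination to a minimal gene set.

    The screen tests each feature against recurrence-free survival
    (``screen="cox"``) or recurrence status (``"logistic"``) at
    ``screen_alpha``.  Survivors enter a joint model of recurrence
    status (logistic) or survival (Cox); the largest-p term is dropped
    until all p < ``retain_alpha``.  Perfectly collinear features are
    removed with a warning before the joint fit.
    """
    df = clinical.data.loc[[p for p in clinical.patient_ids if p in set(m.sample_ids)]]
    cols = [m.sample_index(p) for p in df.index]
    x = m.values[:, cols]
    time = df["time_months"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    if event.sum() < 1:
        raise ValueError("no events")

    screened = []
    for i, fid in enumerate(m.feature_ids):
        if screen == "cox":
            p = _univariate_cox_p(time, event, x[i])
        elif screen == "logistic":
            p = _univariate_logistic_p(event, x[i])
        else:
            raise ValueError(f"unknown screen {screen!r}")
        if p < screen_alpha:
            screened.append(str(fid))
    if not screened:
        warnings.warn("stepwise_select: empty univariate screen")
        return StepwiseResult([], [], {}, screen_alpha, retain_alpha)

    idx = {str(f): i for i, f in enumerate(m.feature_ids)}
    sel = sorted(screened, key=lambda f: idx[f])  # stable feature-ID order
    design = pd.DataFrame({f: x[idx[f]] for f in sel}, index=df.index)

    # drop exact/near collinearity, keeping the earlier feature
    dropped_collinear: list[str] = []
    keep: list[str] = []
    for f in sel:
        cand = design[keep + [f]].to_numpy()
        if keep and np.linalg.matrix_rank(cand - cand.mean(axis=0)) <= len(keep):
            dropped_collinear.append(f)
            warnings.warn(f"stepwise_select: dropping collinear feature {f}")
        else:
            keep.append(f)
    sel = keep

    def joint_pvalues(feats: list[str]) -> pd.Series:
        if final == "logistic":
            X = sm.add_constant(design[feats])
            fit = sm.Logit(event, X).fit(disp=0, maxiter=200)
            return fit.pvalues.drop("const")
        if final == "cox":
            d = design[feats].copy()
            d["time_months"] = time
            d["event"] = event
            cph = CoxPHFitter()
            cph.fit(d, duration_col="time_months", event_col="event")
            return cph.summary["p"]
        raise ValueError(f"unknown final model {final!r}")

    while sel:
        pvals = joint_pvalues(sel)
        worst = pvals.idxmax()
        if pvals[worst] < retain_alpha:
            break
        sel = [f for f in sel if f != worst]

    coefs: dict[str, float] = {}
    if sel:
        if final == "logistic":
            fit = sm.Logit(event, sm.add_constant(design[sel])).fit(disp=0, maxiter=200)
            coefs = {f: float(fit.params[f]) for f in sel}
        else:
            d = design[sel].copy()
            d["time_months"] = time
            d["event"] = event
            cph = CoxPHFitter()
            cph.fit(d, duration_col="time_months", event_col="event")
            coefs = {f: float(cph.params_[f]) for f in sel}
    return StepwiseResult(
        screened_features=screened,
        selected_features=sel,
        coefficients=coefs,
        screen_alpha=screen_alpha,
        retain_alpha=retain_alpha,
        dropped_collinear=dropped_collinear,
    )


# ---------------------------------------------------------------------------
# concordance of reduced vs full models


def model_concordance(
    calls_a: Mapping[str, str] | pd.Series,
    calls_b: Mapping[str, str] | pd.Series,
    correction: bool = True,
) -> tuple[ConcordanceResult, pd.DataFrame]:
    """Cramer's V between two binary call vectors plus the cross-table."""
    a = pd.Series(calls_a).astype(str)
    b = pd.Series(calls_b).astype(str)
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValueError("need >= 2 common patients")
    table = pd.crosstab(a[common], b[common])
    if table.shape != (2, 2):
        raise ValueError(f"expected 2x2 cross-table, got {table.shape}")
    return concordance(table.to_numpy(), correction=correction), table
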