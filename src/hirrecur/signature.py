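"""Injury-signature derivation.

Differential expression uses a random-variance (regularized) t-test:
gene-level precisions are modeled as ``1/sigma^2 ~ Gamma(a, scale=b)``,
fitted across all genes by maximum likelihood, and each gene's variance
is shrunk toward the prior, adding ``2a`` degrees of freedom.  Under the
model ``a * b * s^2 ~ F(m, 2a)`` marginally, which is what the fit
maximizes.

The signature is the intersection of per-dataset significant sets at a
fixed alpha; a label-permutation global test assesses whether the
observed number of significant genes exceeds chance.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from hirrecur.io_preprocess import ExpressionMatrix
from hirrecur.synthetic_data import PairedDesign

__all__ = [
    "GeneTestResult",
    "Signature",
    "VariancePrior",
    "fit_variance_prior",
    "random_variance_ttest",
    "derive_signature",
    "global_permutation_test",
    "GlobalTestResult",
]


@dataclass(frozen=True)
class VariancePrior:
    """Fitted Gamma precision prior (shape ``a``, scale ``b``)."""

    a: float
    b: float
    degenerate: bool = False  # all variances (nearly) equal -> shrinkage ~ 1

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("prior parameters must be positive")


@dataclass(frozen=True)
class GeneTestResult:
    feature_id: str
    t_stat: float
    p_value: float
    df: float
    shrunken_variance: float
    mean_diff: float


@dataclass
class Signature:
    """Ordered feature set with t-statistic weights and provenance."""

    features: list[tuple[str, str, float]]  # (feature_id, gene_symbol, weight)
    alpha: float
    provenance: dict = field(default_factory=dict)

    @property
    def feature_ids(self) -> list[str]:
        return [f for f, _, _ in self.features]

    @property
    def symbols(self) -> list[str]:
        return [s for _, s, _ in self.features]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, _, w in self.features], dtype=float)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_unique_genes(self) -> int:
        return len(set(self.symbols))

    def weight_by_symbol(self) -> dict[str, float]:
        """Collapse probe weights to symbols (sum over probes of a gene)."""
        out: dict[str, float] = {}
        for _, sym, w in self.features:
            out[sym] = out.get(sym, 0.0) + w
        return out

    def subset(self, feature_ids: Sequence[str]) -> "Signature":
        keep = set(feature_ids)
        return Signature(
            features=[f for f in self.features if f[0] in keep],
            alpha=self.alpha,
            provenance={**self.provenance, "subset_of": self.n_features},
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "provenance": self.provenance,
            "features": [
                {"feature_id": f, "gene_symbol": s, "weight": w} for f, s, w in self.features
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Signature":
        payload = json.loads(Path(path).read_text())
        return cls(
            features=[
                (d["feature_id"], d["gene_symbol"], float(d["weight"]))
                for d in payload["features"]
            ],
            alpha=float(payload["alpha"]),
            provenance=payload.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# variance prior


def fit_variance_prior(
    residual_variances: np.ndarray, df_per_gene: int | np.ndarray
) -> VariancePrior:
    """Maximum-likelihood fit of the Gamma precision prior.

    ``residual_variances`` are per-gene sample variances with
    ``df_per_gene`` residual degrees of freedom; marginally
    ``a*b*s^2 ~ F(m, 2a)``.
    """
    s2 = np.asarray(residual_variances, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("negative variances")
    if np.any(s2 == 0):
        raise ValueError("zero variances; cannot fit precision prior")
    if s2.size < 50:
        warnings.warn(f"fit_variance_prior: only {s2.size} genes; fit may be unstable")
    m = np.broadcast_to(np.asarray(df_per_gene, dtype=float), s2.shape)

    degenerate = float(np.ptp(np.log(s2))) < 1e-10
    if degenerate:
        # all variances equal: the likelihood pushes a -> infinity
        # (total shrinkage); return a capped, flagged fit
        a = 1e6
        b = 1.0 / (a * float(s2[0]))
        warnings.warn("fit_variance_prior: degenerate input, shrinkage weight -> 1")
        return VariancePrior(a=a, b=b, degenerate=True)

    def nll(theta: np.ndarray) -> float:
        a, b = np.exp(theta)
        x = a * b * s2
        ll = np.log(a * b) + stats.f.logpdf(x, m, 2.0 * a)
        return -float(np.sum(ll))

    a0 = 2.0
    b0 = 1.0 / (a0 * float(np.mean(s2)))
    res = optimize.minimize(nll, x0=np.log([a0, b0]), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    a, b = np.exp(res.x)
    return VariancePrior(a=float(a), b=float(b))


# ---------------------------------------------------------------------------
# random-variance t-test


def _paired_diffs(m: ExpressionMatrix, design: PairedDesign) -> np.ndarray:
    pre = np.column_stack([m.column(s) for s in design.pre_ids])
    post = np.column_stack([m.column(s) for s in design.post_ids])
    return post - pre


def _two_class_split(
    m: ExpressionMatrix, labels: Sequence[str], ref: str | None
) -> tuple[np.ndarray, np.ndarray, str, str]:
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != m.n_samples:
        raise ValueError("labels length does not match sample count")
    classes = sorted(set(map(str, labels)))
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {classes}")
    ref = classes[0] if ref is None else str(ref)
    if ref not in classes:
        raise ValueError(f"reference class {ref!r} not among {classes}")
    other = classes[0] if classes[1] == ref else classes[1]
    x_ref = m.values[:, labels == ref]
    x_other = m.values[:, labels == other]
    if x_ref.shape[1] < 2 or x_other.shape[1] < 2:
        raise ValueError("each class needs >= 2 samples")
    return x_ref, x_other, ref, other


def _rv_stats(
    mean_diff: np.ndarray, s2: np.ndarray, m_df: float, c: float, prior: VariancePrior
) -> pd.DataFrame:
    shrunk = (m_df * s2 + 2.0 / prior.b) / (m_df + 2.0 * prior.a)
    df = m_df + 2.0 * prior.a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / np.sqrt(shrunk * c)
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {
            "t_stat": t,
            "p_value": np.clip(p, np.finfo(float).tiny, 1.0),
            "df": df,
            "shrunken_variance": shrunk,
            "mean_diff": mean_diff,
        }
    )


def random_variance_ttest(
    m: ExpressionMatrix,
    groups: Sequence[str] | PairedDesign,
    prior: VariancePrior | None = None,
    ref: str | None = None,
) -> pd.DataFrame:
    """Per-gene regularized t-test, paired or two-class.

    Paired (``groups`` a :class:`PairedDesign`): one-sample test on
    post-minus-pre differences, ``m = n_pairs - 1``, ``c = 1/n_pairs``.
    Unpaired: pooled-variance two-sample test with ``m = n1 + n2 - 2``,
    ``c = 1/n1 + 1/n2``; ``mean_diff`` is non-reference minus reference
    class mean (classes sorted, first is reference by default).

    If ``prior`` is None it is fitted from this matrix's residual
    variances.  Returns a DataFrame indexed by feature_id with columns
    t_stat, p_value, df, shrunken_variance, mean_diff.
    """
    if isinstance(groups, PairedDesign):
        if groups.n_pairs < 2:
            raise ValueError("paired test needs >= 2 pairs")
        d = _paired_diffs(m, groups)
        n = d.shape[1]
        mean_diff = d.mean(axis=1)
        s2 = d.var(axis=1, ddof=1)
        m_df, c = float(n - 1), 1.0 / n
    else:
        x_ref, x_other, _, _ = _two_class_split(m, groups, ref)
        n1, n2 = x_ref.shape[1], x_other.shape[1]
        mean_diff = x_other.mean(axis=1) - x_ref.mean(axis=1)
        s2 = (x_ref.var(axis=1, ddof=1) * (n1 - 1) + x_other.var(axis=1, ddof=1) * (n2 - 1)) / (
            n1 + n2 - 2
        )
        m_df, c = float(n1 + n2 - 2), 1.0 / n1 + 1.0 / n2
    if prior is None:
        prior = fit_variance_prior(np.maximum(s2, np.finfo(float).tiny), m_df)
    out = _rv_stats(mean_diff, s2, m_df, c, prior)
    out.insert(0, "feature_id", m.feature_ids)
    return out.set_index("feature_id")


def gene_test_results(table: pd.DataFrame) -> list[GeneTestResult]:
    """View a test table as typed per-gene records."""
    return [
        GeneTestResult(
            feature_id=str(idx),
            t_stat=float(r.t_stat),
            p_value=float(r.p_value),
            df=float(r.df),
            shrunken_variance=float(r.shrunken_variance),
            mean_diff=float(r.mean_diff),
        )
        for idx, r in table.iterrows()
    ]


# ---------------------------------------------------------------------------
# signature derivation


def derive_signature(
    datasets: Sequence[tuple[ExpressionMatrix, PairedDesign | Sequence[str]]],
    alpha: float = 0.005,
) -> Signature:
    """Intersect per-dataset significant gene sets into one signature.

    Each dataset is tested with its own fitted variance prior; a feature
    enters the signature only if significant at ``alpha`` in every
    dataset.  Weights are t-statistics from the pooled paired
    differences across all datasets (or from the first dataset when
    designs are unpaired label vectors).
    """
    if not datasets:
        raise ValueError("need >= 1 dataset")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")

    ref_ids = list(map(str, datasets[0][0].feature_ids))
    for m, _ in datasets[1:]:
        if list(map(str, m.feature_ids)) != ref_ids:
            raise ValueError("datasets must share an identical feature space")

    sig_sets: list[set[str]] = []
    provenance: dict = {"alpha": alpha, "datasets": {}}
    tables = []
    for m, design in datasets:
        tab = random_variance_ttest(m, design)
        tables.append(tab)
        significant = set(tab.index[tab["p_value"] < alpha])
        name = design.name if isinstance(design, PairedDesign) else f"dataset{len(sig_sets) + 1}"
        provenance["datasets"][name] = {
            "n_significant": len(significant),
            "n_samples": m.n_samples,
        }
        sig_sets.append(significant)

    common = set.intersection(*sig_sets)
    if not common:
        warnings.warn("derive_signature: empty intersection")

    # pooled weights: concatenate paired differences across datasets
    all_paired = all(isinstance(d, PairedDesign) for _, d in datasets)
    if all_paired and len(datasets) > 1:
        diffs = np.hstack([_paired_diffs(m, d) for m, d in datasets])
        n = diffs.shape[1]
        prior = fit_variance_prior(
            np.maximum(diffs.var(axis=1, ddof=1), np.finfo(float).tiny), n - 1
        )
        pooled = _rv_stats(diffs.mean(axis=1), diffs.var(axis=1, ddof=1), n - 1, 1.0 / n, prior)
        pooled.index = datasets[0][0].feature_ids
        weight_source = pooled
        provenance["weight_source"] = "pooled_paired_differences"
    else:
        weight_source = tables[0]
        provenance["weight_source"] = "first_dataset"

    ref_m = datasets[0][0]
    sym_of = dict(zip(map(str, ref_m.feature_ids), map(str, ref_m.gene_symbols)))
    ordered = [f for f in map(str, ref_m.feature_ids) if f in common]
    features = [(f, sym_of[f], float(weight_source.loc[f, "t_stat"])) for f in ordered]
    provenance["n_features"] = len(features)
    provenance["n_unique_genes"] = len({s for _, s, _ in features})
    return Signature(features=features, alpha=alpha, provenance=provenance)


# ---------------------------------------------------------------------------
# permutation global test


@dataclass(frozen=True)
class GlobalTestResult:
    global_p: float
    n_significant_observed: int
    n_permutations: int
    exhaustive: bool
    alpha: float


def _count_significant_paired(
    d: np.ndarray, signs: np.ndarray, prior: VariancePrior, alpha: float
) -> int:
    ds = d * signs[None, :]
    n = ds.shape[1]
    mean_diff = ds.mean(axis=1)
    s2 = ds.var(axis=1, ddof=1)
    tab = _rv_stats(mean_diff, s2, n - 1, 1.0 / n, prior)
    return int((tab["p_value"] < alpha).sum())


def _count_significant_unpaired(
    x: np.ndarray, mask_ref: np.ndarray, prior: VariancePrior, alpha: float
) -> int:
    x1 = x[:, mask_ref]
    x2 = x[:, ~mask_ref]
    n1, n2 = x1.shape[1], x2.shape[1]
    mean_diff = x2.mean(axis=1) - x1.mean(axis=1)
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)) / (n1 + n2 - 2)
    tab = _rv_stats(mean_diff, s2, n1 + n2 - 2, 1.0 / n1 + 1.0 / n2, prior)
    return int((tab["p_value"] < alpha).sum())


def global_permutation_test(
    m: ExpressionMatrix,
    groups: Sequence[str] | PairedDesign,
    alpha: float = 0.005,
    n_perm: int = 1000,
    seed: int = 0,
) -> GlobalTestResult:
    """Label-permutation test of the number of significant genes.

    Paired designs permute within pairs (sign flips of the differences);
    unpaired designs permute class labels.  When the number of distinct
    permutations does not exceed ``n_perm`` they are enumerated
    exhaustively and the p-value is the exact proportion; otherwise
    ``n_perm`` random permutations are drawn and the add-one estimator
    ``(1 + #{count >= observed}) / (1 + n_perm)`` is used.

    The variance prior is fitted once on the observed data and held
    fixed across permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    if isinstance(groups, PairedDesign):
        d = _paired_diffs(m, groups)
        n = d.shape[1]
        prior = fit_variance_prior(np.maximum(d.var(axis=1, ddof=1), np.finfo(float).tiny), n - 1)
        observed = _count_significant_paired(d, np.ones(n), prior, alpha)
        n_distinct = 2**n
        if n_distinct <= n_perm:
            counts = [
                _count_significant_paired(d, np.array(signs, dtype=float), prior, alpha)
                for signs in itertools.product((1.0, -1.0), repeat=n)
            ]
            hits = sum(c >= observed for c in counts)
            return GlobalTestResult(hits / n_distinct, observed, n_distinct, True, alpha)
        hits = sum(
            _count_significant_paired(d, rng.choice([1.0, -1.0], size=n), prior, alpha) >= observed
            for _ in range(n_perm)
        )
        return GlobalTestResult((1 + hits) / (1 + n_perm), observed, n_perm, False, alpha)

    x1, x2, ref_label, _ = _two_class_split(m, groups, None)
    labels = np.asarray(groups, dtype=object)
    x = m.values
    mask_ref = np.asarray([str(l) == ref_label for l in labels])
    n1 = int(mask_ref.sum())
    n_total = len(labels)
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (x2.shape[1] - 1)) / (
        n_total - 2
    )
    prior = fit_variance_prior(np.maximum(s2, np.finfo(float).tiny), n_total - 2)
    observed = _count_significant_unpaired(x, mask_ref, prior, alpha)
    n_distinct = math.comb(n_total, n1)
    if n_distinct <= n_perm:
        counts = []
        for combo in itertools.combinations(range(n_total), n1):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(combo)] = True
            counts.append(_count_significant_unpaired(x, mask, prior, alpha))
        hits = sum(c >= observed for c in counts)
        return GlobalTestResult(hits / n_distinct, observed, n_distinct, True, alpha)
    hits = 0
    for _ in range(n_perm):
        mask = np.zeros(n_total, dtype=bool)
        mask[rng.choice(n_total, size=n1, replace=False)] = True
        hits += _count_significant_unpaired(x, mask, prior, alpha) >= observed
    return GlobalTestResult((1 + hits) / (1 + n_perm), observed, n_perm, False, alpha)
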