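"""Synthetic paired-injury datasets and patient cohorts with known truth.

Every downstream stage of the pipeline is testable against the planted
ground truth produced here: which genes respond to injury, each
patient's latent class and tumor score, and the generating hazard
ratios of the piecewise recurrence model.

Gene-level noise variances are drawn under an inverse-gamma model
(precision ``1/sigma^2 ~ Gamma(a, scale=b)``), matching the shrinkage
prior assumed by the random-variance t-test, so calibration tests are
exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from hirrecur.io_preprocess import CohortClinical, ExpressionMatrix

__all__ = [
    "SyntheticConfig",
    "PairedDesign",
    "GroundTruth",
    "generate_paired_datasets",
    "generate_cohort",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass
class PairedDesign:
    """Before/after sample pairing within one named injury dataset."""

    name: str
    pairs: list[tuple[str, str]]  # (pre_sample_id, post_sample_id)

    @property
    def pre_ids(self) -> list[str]:
        return [p for p, _ in self.pairs]

    @property
    def post_ids(self) -> list[str]:
        return [q for _, q in self.pairs]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class SyntheticConfig:
    """Knobs for the paired-dataset and cohort generators.

    Hazard fields parameterize the piecewise-exponential recurrence
    model: before ``cutoff_tau`` the hazard is
    ``early_hazard_base * exp(beta_early * tumor_score)``, after it
    ``late_hazard_base * exp(beta_late * [class == HIR])``.
    """

    n_genes: int = 2000
    n_signature: int = 50
    n_datasets: int = 3
    pairs_per_dataset: int = 10
    prior_shape_a: float = 2.0
    prior_rate_b: float = 4.0  # scale of the Gamma precision prior
    injury_effect: float = 1.5  # log2 shift for planted genes, post vs pre
    pair_correlation: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    cohort_size: int = 400
    prop_hir: float = 0.35
    class_shift_d: float = 1.0
    n_tumor_score_genes: int = 20
    early_hazard_base: float = 0.004  # events / month
    late_hazard_base: float = 0.015
    cutoff_tau: float = 24.0
    beta_early: float = 0.0  # log-HR per unit tumor score, t < tau
    beta_late: float = 0.0  # log-HR HIR vs QT, t >= tau
    censor_max: float = 120.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.n_signature <= self.n_genes:
            raise ValueError("n_signature must satisfy 0 <= n_signature <= n_genes")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if self.pairs_per_dataset < 2:
            raise ValueError("pairs_per_dataset must be >= 2")
        if self.prior_shape_a <= 0:
            raise ValueError("prior_shape_a must be > 0")
        if self.prior_rate_b <= 0:
            raise ValueError("prior_rate_b must be > 0")
        if not 0 <= self.pair_correlation < 1:
            raise ValueError("pair_correlation must lie in [0, 1)")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if not 0 <= self.prop_hir <= 1:
            raise ValueError("prop_hir must lie in [0, 1]")
        if self.n_tumor_score_genes < 0 or self.n_tumor_score_genes > self.n_genes - self.n_signature:
            raise ValueError("n_tumor_score_genes must fit among non-signature genes")
        if self.early_hazard_base <= 0:
            raise ValueError("early_hazard_base must be > 0")
        if self.late_hazard_base <= 0:
            raise ValueError("late_hazard_base must be > 0")
        if self.cutoff_tau <= 0:
            raise ValueError("cutoff_tau must be > 0")
        if self.censor_max <= 0:
            raise ValueError("censor_max must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """What the generator planted; the oracle for recovery tests."""

    planted_signature: list[str] = field(default_factory=list)  # feature IDs
    planted_symbols: list[str] = field(default_factory=list)
    tumor_score_genes: list[str] = field(default_factory=list)
    per_patient_class: dict[str, str] = field(default_factory=dict)  # HIR / QT
    per_patient_tumor_score: dict[str, float] = field(default_factory=dict)
    true_late_hr: float = 1.0
    true_early_hr_per_unit: float = 1.0


def _feature_ids(n: int) -> np.ndarray:
    return np.array([f"FEAT{i:06d}" for i in range(n)], dtype=object)


def _gene_symbols(n: int) -> np.ndarray:
    return np.array([f"GENE{i:06d}" for i in range(n)], dtype=object)


def _planted_indices(config: SyntheticConfig) -> np.ndarray:
    # dedicated stream: the planted set is shared by both generators
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 17)))
    return np.sort(rng.choice(config.n_genes, size=config.n_signature, replace=False))


def _draw_variances(rng: np.random.Generator, config: SyntheticConfig, n: int) -> np.ndarray:
    precision = rng.gamma(shape=config.prior_shape_a, scale=config.prior_rate_b, size=n)
    return 1.0 / precision


def generate_paired_datasets(
    config: SyntheticConfig,
) -> tuple[list[tuple[ExpressionMatrix, PairedDesign]], GroundTruth]:
    """Generate K paired before/after-injury datasets.

    Per dataset: each gene has a baseline mean, a variance drawn from the
    inverse-gamma model, a per-pair Gaussian random intercept (variance
    set so the within-pair correlation equals ``pair_correlation``) and
    i.i.d. noise.  Post-injury samples of planted genes are shifted by
    ``injury_effect`` on the log2 scale.
    """
    config.validate()
    feature_ids = _feature_ids(config.n_genes)
    symbols = _gene_symbols(config.n_genes)
    planted = _planted_indices(config)
    delta = np.zeros(config.n_genes)
    delta[planted] = config.injury_effect

    datasets: list[tuple[ExpressionMatrix, PairedDesign]] = []
    rho = config.pair_correlation
    for k in range(config.n_datasets):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0, k)))
        n_pairs = config.pairs_per_dataset
        mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
        sigma2 = _draw_variances(rng, config, config.n_genes)
        sigma = np.sqrt(sigma2)
        pair_sd = np.sqrt(sigma2 * rho / (1.0 - rho))
        pair_effect = rng.normal(0.0, 1.0, size=(config.n_genes, n_pairs)) * pair_sd[:, None]
        pre = (
            mu[:, None]
            + pair_effect
            + rng.normal(0.0, 1.0, size=(config.n_genes, n_pairs)) * sigma[:, None]
        )
        post = (
            mu[:, None]
            + pair_effect
            + delta[:, None]
            + rng.normal(0.0, 1.0, size=(config.n_genes, n_pairs)) * sigma[:, None]
        )
        name = f"injury{k + 1}"
        pre_ids = [f"{name}_pre{p + 1:02d}" for p in range(n_pairs)]
        post_ids = [f"{name}_post{p + 1:02d}" for p in range(n_pairs)]
        m = ExpressionMatrix(
            feature_ids=feature_ids,
            gene_symbols=symbols,
            sample_ids=np.array(pre_ids + post_ids, dtype=object),
            values=np.hstack([pre, post]),
        )
        datasets.append((m, PairedDesign(name=name, pairs=list(zip(pre_ids, post_ids)))))

    truth = GroundTruth(
        planted_signature=[str(f) for f in feature_ids[planted]],
        planted_symbols=[str(s) for s in symbols[planted]],
    )
    return datasets, truth


def _piecewise_exponential_times(
    rng: np.random.Generator,
    rate_early: np.ndarray,
    rate_late: np.ndarray,
    tau: float,
) -> np.ndarray:
    """Invert the cumulative hazard of the two-piece exponential model."""
    u = rng.uniform(size=rate_early.shape)
    target = -np.log(u)
    t = target / rate_early
    spill = t >= tau
    t[spill] = tau + (target[spill] - rate_early[spill] * tau) / rate_late[spill]
    return t


def generate_cohort(
    config: SyntheticConfig,
    signature_features: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, CohortClinical, GroundTruth]:
    """Generate one HCC cohort: adjacent tissue, tumor tissue and clinical table.

    Latent class HIR/QT shifts ``signature_features`` (default: the
    planted injury genes for this config/seed) by ``class_shift_d`` in
    adjacent tissue.  A standard-normal tumor score loads on dedicated
    tumor genes.  Recurrence times follow the piecewise-exponential
    hazard described on :class:`SyntheticConfig`; censoring is
    Uniform(0, censor_max), independent of class and score.
    """
    config.validate()
    feature_ids = _feature_ids(config.n_genes)
    symbols = _gene_symbols(config.n_genes)
    id_to_idx = {str(f): i for i, f in enumerate(feature_ids)}

    planted = _planted_indices(config)
    if signature_features is None:
        sig_idx = planted
    else:
        missing = [f for f in signature_features if str(f) not in id_to_idx]
        if missing:
            raise ValueError(f"signature features not among generated genes: {missing}")
        sig_idx = np.array([id_to_idx[str(f)] for f in signature_features], dtype=int)

    non_sig = np.setdiff1d(np.arange(config.n_genes), sig_idx)
    tumor_idx = non_sig[: config.n_tumor_score_genes]

    gene_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    mu = gene_rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    sigma = np.sqrt(_draw_variances(gene_rng, config, config.n_genes))

    n = config.cohort_size
    adjacent = np.empty((config.n_genes, n))
    tumor = np.empty((config.n_genes, n))
    classes: list[str] = []
    scores = np.empty(n)
    times = np.empty(n)
    events = np.empty(n, dtype=int)
    cov_rows = []
    patient_ids = [f"P{i + 1:04d}" for i in range(n)]

    for i in range(n):
        # one stream per patient: adding patients never perturbs earlier draws
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2, i)))
        is_hir = rng.uniform() < config.prop_hir
        r_i = rng.normal()
        classes.append("HIR" if is_hir else "QT")
        scores[i] = r_i

        col = mu + rng.normal(0.0, 1.0, size=config.n_genes) * sigma
        if is_hir:
            col[sig_idx] = col[sig_idx] + config.class_shift_d
        adjacent[:, i] = col

        tcol = mu + rng.normal(0.0, 1.0, size=config.n_genes) * sigma
        tcol[tumor_idx] = tcol[tumor_idx] + r_i
        tumor[:, i] = tcol

        rate_early = config.early_hazard_base * np.exp(config.beta_early * r_i)
        rate_late = config.late_hazard_base * np.exp(config.beta_late * float(is_hir))
        t_rec = _piecewise_exponential_times(
            rng, np.array([rate_early]), np.array([rate_late]), config.cutoff_tau
        )[0]
        c = rng.uniform(0.0, config.censor_max)
        times[i] = max(min(t_rec, c), 1e-6)
        events[i] = int(t_rec <= c)

        cov_rows.append(
            {
                "sex": "M" if rng.uniform() < 0.8 else "F",
                "age": round(float(rng.normal(55.0, 10.0)), 1),
                "afp_gt_300": int(rng.uniform() < 0.35),
                "hbv": int(rng.uniform() < 0.8),
                "cirrhosis": int(rng.uniform() < 0.6),
                "tumor_gt_5cm": int(rng.uniform() < 0.3),
                "multinodular": int(rng.uniform() < 0.2),
                "vascular_invasion": int(rng.uniform() < 0.3),
                "bclc": rng.choice(["0", "A", "B", "C"], p=[0.1, 0.55, 0.2, 0.15]),
            }
        )

    sample_ids = np.array(patient_ids, dtype=object)
    adj_m = ExpressionMatrix(feature_ids, symbols, sample_ids, adjacent)
    tum_m = ExpressionMatrix(feature_ids, symbols, sample_ids, tumor)

    clin_df = pd.DataFrame(cov_rows, index=pd.Index(patient_ids, name="patient_id"))
    clin_df.insert(0, "time_months", times)
    clin_df.insert(1, "event", events)
    clinical = CohortClinical(clin_df)

    truth = GroundTruth(
        planted_signature=[str(f) for f in feature_ids[sig_idx]],
        planted_symbols=[str(s) for s in symbols[sig_idx]],
        tumor_score_genes=[str(s) for s in symbols[tumor_idx]],
        per_patient_class=dict(zip(patient_ids, classes)),
        per_patient_tumor_score={p: float(s) for p, s in zip(patient_ids, scores)},
        true_late_hr=float(np.exp(config.beta_late)),
        true_early_hr_per_unit=float(np.exp(config.beta_early)),
    )
    return adj_m, tum_m, clinical, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(truth), indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth(**json.loads(Path(path).read_text()))
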