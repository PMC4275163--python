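import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hirrecur import bccp
from hirrecur.io_preprocess import match_and_center
from hirrecur.signature import Signature, derive_signature
from hirrecur.synthetic_data import SyntheticConfig, generate_cohort, generate_paired_datasets

from conftest import make_matrix


class TestCompoundCovariate:
    def test_hand_arithmetic(self):
        assert bccp.compound_covariate(np.array([2.0, -1.0]), np.array([1.0, 3.0])) == -1.0

    def test_zero_weights(self):
        assert bccp.compound_covariate(np.zeros(5), np.arange(5.0)) == 0.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_linearity(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.normal(size=10)
        x, y = rng.normal(size=10), rng.normal(size=10)
        cx = bccp.compound_covariate(w, x)
        cy = bccp.compound_covariate(w, y)
        assert bccp.compound_covariate(w, x + y) == pytest.approx(cx + cy)

    def test_misaligned_errors(self):
        with pytest.raises(ValueError, match="aligned"):
            bccp.compound_covariate(np.ones(3), np.ones(4))


def _symmetric_training():
    # HIR samples mirror QT samples around 0
    vals = np.array([[1.0, 2.0, -1.0, -2.0], [0.5, 1.5, -0.5, -1.5]])
    m = make_matrix(vals)
    return m, ["HIR", "HIR", "QT", "QT"]


class TestTrainBCCP:
    def test_symmetric_means(self):
        m, labels = _symmetric_training()
        model = bccp.train_bccp(m, labels, np.array([1.0, 1.0]))
        assert model.class_means[0] == pytest.approx(-model.class_means[1])

    def test_single_class_errors(self):
        m, _ = _symmetric_training()
        with pytest.raises(ValueError, match="HIR"):
            bccp.train_bccp(m, ["QT"] * 4, np.ones(2))

    def test_zero_variance_errors(self):
        vals = np.tile([[1.0, 1.0, 0.0, 0.0]], (2, 1))
        m = make_matrix(vals)
        with pytest.raises(ValueError, match="variance"):
            bccp.train_bccp(m, ["HIR", "HIR", "QT", "QT"], np.ones(2))

    def test_separation_grows_with_effect(self):
        seps = []
        for effect in (0.5, 1.5, 3.0):
            cfg = SyntheticConfig(n_genes=60, n_signature=15, n_datasets=1,
                                  pairs_per_dataset=10, injury_effect=effect,
                                  prior_rate_b=4.0, seed=1)
            (m, design), = generate_paired_datasets(cfg)[0]
            labels = ["QT"] * design.n_pairs + ["HIR"] * design.n_pairs
            ordered = m.subset_samples(design.pre_ids + design.post_ids)
            sig = derive_signature([(m, design)], alpha=1.0)
            model = bccp.train_bccp(ordered, labels, sig)
            m_h, m_q = model.class_means
            seps.append(abs(m_h - m_q) / np.sqrt(model.pooled_variance))
        assert seps[0] < seps[1] < seps[2]


class TestPosterior:
    def test_midpoint_is_half(self):
        model = bccp.BCCPModel(
            weights=np.ones(1), feature_order=np.array(["f"]), symbols=np.array(["g"]),
            class_means=(1.0, 3.0), pooled_variance=2.0,
        )
        assert bccp.posterior(model, 2.0) == pytest.approx(0.5)

    def test_gaussian_density_oracle(self):
        # phi(0;0,1)/(phi(0;0,1)+phi(0;2,1)) = 0.3989/(0.3989+0.05399)
        model = bccp.BCCPModel(
            weights=np.ones(1), feature_order=np.array(["f"]), symbols=np.array(["g"]),
            class_means=(0.0, 2.0), pooled_variance=1.0,
        )
        assert bccp.posterior(model, 0.0) == pytest.approx(0.8808, abs=5e-5)

    def test_monotone_decreasing_when_qt_above(self):
        model = bccp.BCCPModel(
            weights=np.ones(1), feature_order=np.array(["f"]), symbols=np.array(["g"]),
            class_means=(0.0, 2.0), pooled_variance=1.0,
        )
        grid = bccp.posterior(model, np.linspace(-3, 5, 50))
        assert (np.diff(grid) < 0).all()

    def test_complement_sums_to_one(self):
        model = bccp.BCCPModel(
            weights=np.ones(1), feature_order=np.array(["f"]), symbols=np.array(["g"]),
            class_means=(-1.0, 1.5), pooled_variance=0.7, priors=(0.3, 0.7),
        )
        flipped = bccp.BCCPModel(
            weights=np.ones(1), feature_order=np.array(["f"]), symbols=np.array(["g"]),
            class_means=(1.5, -1.0), pooled_variance=0.7, priors=(0.7, 0.3),
        )
        for c in (-5.0, 0.0, 2.0, 40.0):
            assert bccp.posterior(model, c) + bccp.posterior(flipped, c) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_finite_everywhere(self):
        model = bccp.BCCPModel(
            weights=np.ones(1), feature_order=np.array(["f"]), symbols=np.array(["g"]),
            class_means=(0.0, 2.0), pooled_variance=1.0,
        )
        for c in (-1e6, 1e6):
            p = bccp.posterior(model, c)
            assert np.isfinite(p) and 0.0 <= p <= 1.0


def _trained_on_synthetic(seed=2, d=1.0, cohort_size=400):
    cfg = SyntheticConfig(
        n_genes=120, n_signature=25, n_datasets=2, pairs_per_dataset=10,
        injury_effect=1.5, prior_rate_b=8.0, class_shift_d=d,
        cohort_size=cohort_size, seed=seed,
    )
    datasets, _ = generate_paired_datasets(cfg)
    sig = derive_signature(datasets, alpha=0.005)
    mats, labels = [], []
    for m, design in datasets:
        mats.append(m.subset_samples(design.pre_ids + design.post_ids))
        labels += ["QT"] * design.n_pairs + ["HIR"] * design.n_pairs
    from hirrecur.io_preprocess import ExpressionMatrix

    pooled = ExpressionMatrix(
        feature_ids=mats[0].feature_ids,
        gene_symbols=mats[0].gene_symbols,
        sample_ids=np.concatenate([m.sample_ids for m in mats]),
        values=np.hstack([m.values for m in mats]),
    )
    training, _ = match_and_center(pooled, sig)
    model = bccp.train_bccp(training, labels, sig.subset(list(training.feature_ids)))
    adj, _, _, truth = generate_cohort(cfg)
    return cfg, sig, model, training, labels, adj, truth


class TestClassifyCohort:
    def test_replicated_training_sample_all_hir(self):
        m, labels = _symmetric_training()
        model = bccp.train_bccp(m, labels, np.array([1.0, 1.0]))
        hir_col = m.values[:, [0]]
        cohort = make_matrix(np.repeat(hir_col, 5, axis=1))
        out = bccp.classify_cohort(model, cohort)
        assert (out["label"] == "HIR").all()

    def test_synthetic_recovery_accuracy(self):
        cfg, sig, model, *_ , adj, truth = _trained_on_synthetic(d=1.0)
        matched, _ = match_and_center(adj, sig)
        out = bccp.classify_cohort(model, matched)
        truth_labels = np.array([truth.per_patient_class[p] for p in out.index])
        acc = float((out["label"].to_numpy() == truth_labels).mean())
        assert acc >= 0.9

    def test_zero_coverage_errors(self):
        m, labels = _symmetric_training()
        model = bccp.train_bccp(m, labels, np.array([1.0, 1.0]))
        cohort = make_matrix([[0.0, 0.0]], feature_ids=["zz"], symbols=["zz"])
        with pytest.raises(ValueError, match="no model features"):
            bccp.classify_cohort(model, cohort)

    def test_low_coverage_warns(self):
        vals = np.random.default_rng(3).normal(size=(4, 6))
        m = make_matrix(vals)
        model = bccp.train_bccp(m, ["HIR", "HIR", "HIR", "QT", "QT", "QT"], np.ones(4))
        cohort = make_matrix(vals[:1], feature_ids=["F0"], symbols=["G0"])
        with pytest.warns(UserWarning, match="coverage"):
            bccp.classify_cohort(model, cohort)

    def test_weight_doubling_leaves_labels_unchanged(self):
        cfg, sig, model, training, labels, adj, _ = _trained_on_synthetic(d=1.0)
        matched, _ = match_and_center(adj, sig)
        out1 = bccp.classify_cohort(model, matched)
        doubled = Signature(
            features=[(f, s, 2 * w) for f, s, w in sig.features], alpha=sig.alpha
        )
        model2 = bccp.train_bccp(training, labels, doubled.subset(list(training.feature_ids)))
        out2 = bccp.classify_cohort(model2, matched)
        assert (out1["label"] == out2["label"]).all()


class TestLOOCV:
    def test_perfectly_separated_zero_error(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(5, 10)) * 0.1
        vals[:, 5:] += 10.0
        m = make_matrix(vals)
        labels = ["QT"] * 5 + ["HIR"] * 5
        _, err = bccp.loocv(m, labels, np.ones(5))
        assert err == 0.0

    def test_permuted_labels_error_near_half(self):
        rng = np.random.default_rng(5)
        errs = []
        for rep in range(10):
            vals = rng.normal(size=(10, 16))
            m = make_matrix(vals)
            labels = list(rng.permutation(["QT"] * 8 + ["HIR"] * 8))
            _, err = bccp.loocv(m, labels, rng.normal(size=10))
            errs.append(err)
        assert 0.3 < np.mean(errs) < 0.7

    def test_loocv_not_more_optimistic_than_resubstitution(self):
        rng = np.random.default_rng(6)
        diffs = []
        for rep in range(50):
            vals = rng.normal(size=(8, 14))
            vals[:, 7:] += 0.4  # weak signal: resubstitution overfits
            m = make_matrix(vals)
            labels = ["QT"] * 7 + ["HIR"] * 7
            w = np.ones(8)
            model = bccp.train_bccp(m, labels, w)
            resub = bccp.classify_cohort(model, m)
            resub_err = float((resub["label"].to_numpy() != np.array(labels)).mean())
            _, cv_err = bccp.loocv(m, labels, w)
            diffs.append(cv_err - resub_err)
        assert np.mean(diffs) >= 0.0

    def test_loocv_approaches_bayes_error_at_high_separation(self):
        cfg, sig, model, training, labels, *_ = _trained_on_synthetic(seed=7)
        _, err = bccp.loocv(training, labels, sig.subset(list(training.feature_ids)))
        m_h, m_q = model.class_means
        from scipy.stats import norm

        bayes = float(norm.sf(abs(m_h - m_q) / (2 * np.sqrt(model.pooled_variance))))
        assert err <= bayes + 0.1

    def test_weights_recompute_runs(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(6, 12))
        vals[:3, 6:] += 2.0
        m = make_matrix(vals)
        labels = ["QT"] * 6 + ["HIR"] * 6
        preds, err = bccp.loocv(m, labels, np.ones(6), weights_recompute=True)
        assert len(preds) == 12
        assert err <= 0.25

    def test_too_few_samples(self):
        m = make_matrix([[1.0, 2.0]])
        with pytest.raises(ValueError, match=">= 3"):
            bccp.loocv(m, ["HIR", "QT"], np.ones(1))
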