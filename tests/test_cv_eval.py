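"""Fold plans, metric formulas, corrected comparison, CV protocol."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import fncxplain as fx
from fncxplain.cv_eval import ConfusionCounts, corrected_paired_test, make_folds, metrics
from fncxplain.models import ForestModel


class TestMakeFolds:
    def test_balanced_hundred_rows_give_five_plus_five_per_fold(self):
        labels = np.r_[np.zeros(50), np.ones(50)]
        plan = make_folds(labels, k=10, seed=0)
        for fold in range(10):
            te = plan.test_rows(fold)
            assert len(te) == 10
            assert (labels[te] == 0).sum() == 5
            assert (labels[te] == 1).sum() == 5

    def test_same_seed_reproduces_the_plan(self):
        labels = np.r_[np.zeros(31), np.ones(40)]
        p1 = make_folds(labels, 10, seed=4)
        p2 = make_folds(labels, 10, seed=4)
        assert np.array_equal(p1.assignments, p2.assignments)

    def test_folds_partition_all_rows(self):
        labels = np.r_[np.zeros(23), np.ones(29)]
        plan = make_folds(labels, 5, seed=1)
        seen = np.concatenate([plan.test_rows(f) for f in range(5)])
        assert sorted(seen) == list(range(52))

    def test_stratification_keeps_class_proportions_within_one(self):
        labels = np.r_[np.zeros(151), np.ones(160)]
        plan = make_folds(labels, 10, seed=2)
        for fold in range(10):
            te = plan.test_rows(fold)
            assert (labels[te] == 0).sum() in (15, 16)
            assert (labels[te] == 1).sum() == 16

    def test_class_smaller_than_k_is_an_error(self):
        labels = np.r_[np.zeros(5), np.ones(50)]
        with pytest.raises(ValueError, match="10-fold"):
            make_folds(labels, 10, seed=0)


class TestMetrics:
    def test_symmetric_confusion_table_gives_half_everywhere(self):
        ms = metrics(ConfusionCounts(tp=25, fn=25, tn=25, fp=25))
        assert (ms.accuracy, ms.sensitivity, ms.specificity, ms.f1) == (0.5, 0.5, 0.5, 0.5)

    def test_hand_computed_confusion_table(self):
        ms = metrics(ConfusionCounts(tp=40, fn=10, tn=45, fp=5))
        assert ms.accuracy == pytest.approx(0.85)
        assert ms.sensitivity == pytest.approx(0.80)
        assert ms.specificity == pytest.approx(0.90)
        assert ms.f1 == pytest.approx(0.8421, abs=1e-4)

    def test_formulas_on_a_thousand_random_tables(self, rng):
        for _ in range(1000):
            tp, fn, tn, fp = rng.integers(0, 50, size=4)
            if tp + fn + tn + fp == 0:
                continue
            ms = metrics(ConfusionCounts(int(tp), int(fn), int(tn), int(fp)))
            assert ms.accuracy == pytest.approx((tp + tn) / (tp + fn + tn + fp))
            if tp + fn:
                assert ms.sensitivity == pytest.approx(tp / (tp + fn))
            else:
                assert np.isnan(ms.sensitivity)
            if tn + fp:
                assert ms.specificity == pytest.approx(tn / (tn + fp))
            else:
                assert np.isnan(ms.specificity)
            if 2 * tp + fp + fn:
                assert ms.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))
            else:
                assert np.isnan(ms.f1)

    def test_auc_extremes(self):
        labels = np.array([0, 0, 1, 1])
        counts = ConfusionCounts(2, 0, 2, 0)
        assert metrics(counts, np.array([0.1, 0.2, 0.8, 0.9]), labels).auc == 1.0
        assert metrics(counts, np.array([0.9, 0.8, 0.2, 0.1]), labels).auc == 0.0
        assert metrics(counts, np.array([0.5, 0.5, 0.5, 0.5]), labels).auc == 0.5

    def test_auc_equals_concordant_pair_fraction(self):
        scores = np.array([0.9, 0.1, 0.8, 0.3, 0.55, 0.55, 0.7, 0.2])
        labels = np.array([1, 0, 1, 0, 1, 0, 0, 1])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum((p > n) + 0.5 * (p == n) for p, n in itertools.product(pos, neg))
        expected = conc / (len(pos) * len(neg))
        counts = ConfusionCounts.from_predictions(labels, (scores >= 0.5).astype(int))
        assert metrics(counts, scores, labels).auc == pytest.approx(expected)


class TestCorrectedPairedTest:
    def test_identical_vectors_give_t_zero_p_one(self):
        a = np.array([0.8, 0.7, 0.9, 0.75])
        t, p = corrected_paired_test(a, a.copy(), n_train=90, n_test=10)
        assert (t, p) == (0.0, 1.0)

    def test_constant_difference_with_tiny_noise_is_significant(self, rng):
        b = 0.7 + rng.normal(0, 1e-4, size=10)
        a = b + 0.1
        t, p = corrected_paired_test(a, b, n_train=90, n_test=10)
        assert p < 0.01

    def test_correction_never_exceeds_naive_t(self, rng):
        for _ in range(20):
            a = rng.uniform(0.5, 1.0, size=10)
            b = rng.uniform(0.5, 1.0, size=10)
            if np.var(a - b) == 0:
                continue
            t_corr, _ = corrected_paired_test(a, b, n_train=90, n_test=10)
            t_naive = sps.ttest_rel(a, b).statistic
            assert abs(t_corr) <= abs(t_naive) + 1e-12


def tiny_table(seed=0, delta=1.2):
    cfg = fx.SyntheticConfig(n_class1=40, n_class2=44, n_features=60,
                             planted_blocks=((5, 10), (30, 35)), effect_delta=delta,
                             with_covariates=True, seed=seed)
    return fx.generate_features(cfg)


def tiny_forest():
    return ForestModel(n_trees=15, max_depth=6)


class TestRunRepeatedCv:
    def test_single_iteration_equals_manual_composition(self):
        """The orchestrated run must reproduce a by-hand single CV pass."""
        table, _ = tiny_table()
        res = fx.run_repeated_cv(table, {"forest": tiny_forest}, k=4, iterations=1,
                                 confound_cols=["age", "sex", "site"], seed=5)
        # re-derive the seeds exactly as the runner does
        root = np.random.SeedSequence(5)
        fold_ss, fit_ss = root.spawn(2)
        fold_rng = np.random.default_rng(fold_ss)
        fit_rng = np.random.default_rng(fit_ss)
        plan = fx.make_folds(table.y, 4, seed=int(fold_rng.integers(2**31)))
        from fncxplain.confounds import apply_residualizer, fit_residualizer
        fold0_tr, fold0_te = plan.train_rows(0), plan.test_rows(0)
        cov = table.frame[["age", "sex", "site"]]
        cm = fit_residualizer(table.X[fold0_tr], cov.iloc[fold0_tr], ["age", "sex", "site"])
        X_tr = apply_residualizer(cm, table.X[fold0_tr], cov.iloc[fold0_tr])
        X_te = apply_residualizer(cm, table.X[fold0_te], cov.iloc[fold0_te])
        model = tiny_forest().fit(X_tr, table.y[fold0_tr], seed=int(fit_rng.integers(2**31)))
        scores = model.predict_proba(X_te)
        manual_acc = np.mean((scores >= 0.5).astype(int) == table.y[fold0_te])
        row = res.metrics[(res.metrics["fold"] == 0)].iloc[0]
        assert row["accuracy"] == pytest.approx(manual_acc)

    def test_planted_signal_is_learned_above_chance(self):
        table, _ = tiny_table(delta=1.2)
        res = fx.run_repeated_cv(table, {"forest": tiny_forest}, k=4, iterations=2,
                                 confound_cols=[], seed=1)
        assert res.mean_metric("forest") > 0.8

    def test_label_permutation_destroys_the_signal(self):
        table, _ = tiny_table(delta=1.2)
        rng = np.random.default_rng(3)
        df = table.frame.copy()
        df["label"] = rng.permutation(df["label"].to_numpy())
        shuffled = fx.LabeledFeatureTable(df, table.covariate_cols)
        res = fx.run_repeated_cv(shuffled, {"forest": tiny_forest}, k=4, iterations=3,
                                 confound_cols=[], seed=2)
        accs = res.metrics["accuracy"].to_numpy()
        # 12 fold-level accuracies on ~21-row test folds: mean within 3 SD of chance
        assert abs(accs.mean() - 0.5) < 3 * accs.std(ddof=1) / np.sqrt(len(accs))

    def test_attributions_cover_every_row_once_per_iteration(self):
        table, _ = tiny_table()
        res = fx.run_repeated_cv(table, {"forest": tiny_forest}, k=4, iterations=2,
                                 confound_cols=[], seed=0)
        acc = res.attributions["forest"]
        assert len(acc.subject_ids) == 2 * len(table.frame)
        X, phi = acc.stacked()
        assert X.shape == phi.shape == (2 * len(table.frame), table.n_features)

    def test_test_rows_never_reach_the_fitted_model(self):
        """Leakage audit: poisoning held-out labels and features after the
        split leaves the fitted model's training predictions unchanged."""
        table, _ = tiny_table()
        plan = fx.make_folds(table.y, 4, seed=0)
        tr = plan.train_rows(0)
        te = plan.test_rows(0)
        model_clean = tiny_forest().fit(table.X[tr], table.y[tr], seed=9)
        X_poisoned = table.X.copy()
        X_poisoned[te] = 1e6  # absurd held-out values
        model_poisoned = tiny_forest().fit(X_poisoned[tr], table.y[tr], seed=9)
        assert np.array_equal(model_clean.predict_proba(table.X[tr]),
                              model_poisoned.predict_proba(table.X[tr]))

    def test_stage_errors_carry_the_stage_tag(self):
        table, _ = tiny_table()
        class Broken:
            def fit(self, *a, **k):
                raise FloatingPointError("boom")
        with pytest.raises(RuntimeError, match=r"\[fit:bad\]"):
            fx.run_repeated_cv(table, {"bad": Broken}, k=4, iterations=1,
                               confound_cols=[], seed=0)
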