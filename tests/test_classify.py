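"""Splitting, forest training, metric panel, bootstrap and ablation."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import precision_recall_fscore_support

import spinefuse as sf
from spinefuse.classify import (RFConfig, bootstrap_ci, compute_metrics,
                                crossval, evaluate_predictions, run_ablation,
                                split_dataset, train_rf)


def sklearn_panel(y_true, y_pred, labels):
    """Independent metric oracle built on sklearn primitives."""
    _, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0)
    cm = sk_confusion(y_true, y_pred, labels=labels)
    n = cm.sum()
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = n - tp - fp - fn
    spec = np.where(tn + fp > 0, tn / (tn + fp), 0.0).mean()
    return {"accuracy": (np.asarray(y_true) == np.asarray(y_pred)).mean(),
            "sensitivity": rec, "specificity": spec, "f1": f1}


class TestSplitDataset:
    def test_balanced_100_gives_70_15_15(self):
        y = np.repeat(np.arange(4), 25)
        plan = split_dataset(y, seed=0)
        assert plan.sizes == (70, 15, 15)

    def test_study_scale_counts(self):
        """93/118/105 cases split to 221/47/48 overall, with per-class
        proportions within one case of 70/15/15."""
        y = np.concatenate([np.repeat("a", 93), np.repeat("e", 118),
                            np.repeat("h", 105)])
        plan = split_dataset(y, seed=3)
        assert plan.sizes == (221, 47, 48)
        for cls, n_c in (("a", 93), ("e", 118), ("h", 105)):
            n_tr = (y[plan.train_idx] == cls).sum()
            assert abs(n_tr - 0.70 * n_c) <= 1

    def test_determinism_and_disjointness(self):
        y = np.repeat([0, 1, 2], 10)
        a = split_dataset(y, seed=5)
        b = split_dataset(y, seed=5)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)
        all_idx = np.concatenate([a.train_idx, a.val_idx, a.test_idx])
        assert sorted(all_idx) == list(range(30))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            split_dataset(np.array([0, 0, 0, 1, 1]))


class TestTrainRf:
    def test_separable_fixture_fits_perfectly(self):
        fx = sf.make_feature_fixture(30, 3, 3, 2, effect_size=6.0, seed=0)
        model = train_rf(fx.X, fx.y, RFConfig(seed=0))
        assert (model.predict(fx.X) == fx.y).mean() == 1.0

    def test_seeded_determinism(self):
        fx = sf.make_feature_fixture(20, 2, 2, 6, effect_size=1.0, seed=1)
        held = sf.make_feature_fixture(10, 2, 2, 6, effect_size=1.0, seed=9)
        p1 = train_rf(fx.X, fx.y, RFConfig(seed=4)).predict(held.X)
        p2 = train_rf(fx.X, fx.y, RFConfig(seed=4)).predict(held.X)
        np.testing.assert_array_equal(p1, p2)

    def test_probabilities_normalized(self):
        fx = sf.make_feature_fixture(10, 3, 2, 2, effect_size=2.0, seed=2)
        prob = train_rf(fx.X, fx.y, RFConfig(seed=0)).predict_proba(fx.X)
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_rf(np.zeros((5, 2)), np.zeros(5), RFConfig())

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            RFConfig(n_trees=0)
        with pytest.raises(ValueError):
            RFConfig(max_depth=0)


class TestComputeMetrics:
    def test_worked_counting_example(self):
        y_true = [0, 0, 1, 1, 2, 2]
        y_pred = [0, 1, 1, 1, 2, 0]
        m = compute_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(4 / 6)
        assert m["sensitivity"] == pytest.approx((1 / 2 + 1 + 1 / 2) / 3)
        assert m["specificity"] == pytest.approx((3 / 4 + 3 / 4 + 4 / 4) / 3)

    def test_perfect_probabilistic_prediction(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        prob = np.eye(3)[y]
        m = compute_metrics(y, y, prob)
        assert m["auc"] == 1.0
        assert m["f1"] == 1.0
        assert m["accuracy"] == 1.0

    def test_exhaustive_against_sklearn_oracle_short_vectors(self):
        """Panel equals the sklearn-based confusion-matrix oracle for every
        (y_true, y_pred) pair of length 3 and 4 over 3 classes with at
        least two classes present in y_true."""
        labels = [0, 1, 2]
        for n in (3, 4):
            for y_true in itertools.product(labels, repeat=n):
                if len(set(y_true)) < 2:
                    continue
                present = sorted(set(y_true))
                for y_pred in itertools.product(present, repeat=n):
                    m = compute_metrics(list(y_true), list(y_pred),
                                        classes=present)
                    o = sklearn_panel(y_true, y_pred, present)
                    for k in o:
                        assert m[k] == pytest.approx(o[k]), (y_true, y_pred)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_length8_vectors_against_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            y_true = rng.integers(0, 3, 8)
            if len(np.unique(y_true)) < 2:
                continue
            present = sorted(np.unique(y_true))
            y_pred = rng.choice(present, 8)
            m = compute_metrics(y_true, y_pred, classes=present)
            o = sklearn_panel(y_true, y_pred, present)
            for k in o:
                assert m[k] == pytest.approx(o[k])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0])


class TestBootstrapCi:
    def test_degenerate_perfect_predictions(self):
        y = np.repeat([0, 1], 10)
        lo, hi = bootstrap_ci("accuracy", y, y, B=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_bounds_ordered_and_in_unit_interval(self, rng):
        y_true = rng.integers(0, 3, 40)
        y_pred = rng.integers(0, 3, 40)
        for metric in ("accuracy", "sensitivity", "specificity", "f1"):
            lo, hi = bootstrap_ci(metric, y_true, y_pred, B=150, seed=1)
            assert 0 <= lo <= hi <= 1

    def test_coverage_of_true_accuracy(self):
        """The 95% interval covers the true accuracy 0.8 in >= 90 of 100
        simulated prediction sets (n=200, balanced binary)."""
        rng = np.random.default_rng(0)
        covered = 0
        for rep in range(100):
            y_true = np.tile([0, 1], 100)
            correct = rng.random(200) < 0.8
            y_pred = np.where(correct, y_true, 1 - y_true)
            lo, hi = bootstrap_ci("accuracy", y_true, y_pred, B=200,
                                  seed=rep)
            covered += lo <= 0.8 <= hi
        assert covered >= 90

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci("accuracy", [0, 1], [0, 1], B=10)


class TestCrossval:
    def test_permuted_labels_stay_at_chance(self):
        fx = sf.make_feature_fixture(30, 3, 4, 4, effect_size=3.0, seed=0)
        y_perm = np.random.default_rng(1).permutation(fx.y)
        _, summary = crossval(fx.X, y_perm, RFConfig(n_trees=25, seed=0),
                              k=5, seed=0)
        sd = np.sqrt((1 / 3) * (2 / 3) / 90)
        assert abs(summary["accuracy"]["mean"] - 1 / 3) <= 3 * sd

    def test_leave_one_out_boundary(self):
        fx = sf.make_feature_fixture(6, 2, 2, 1, effect_size=4.0, seed=2)
        rows, _ = crossval(fx.X, fx.y, RFConfig(n_trees=10, seed=0), k=12,
                           seed=0)
        assert len(rows) == 12

    def test_fold_stratification(self):
        fx = sf.make_feature_fixture(20, 3, 2, 2, effect_size=2.0, seed=3)
        from sklearn.model_selection import StratifiedKFold
        for _, te in StratifiedKFold(5, shuffle=True,
                                     random_state=0).split(fx.X, fx.y):
            _, counts = np.unique(fx.y[te], return_counts=True)
            assert (np.abs(counts - 4) <= 1).all()

    def test_selection_runs_inside_training_folds_only(self):
        """No leakage: the selector only ever sees training-fold data, and
        permuting held-out labels leaves the selected mask unchanged."""
        fx = sf.make_feature_fixture(15, 2, 2, 4, effect_size=3.0, seed=4)
        seen_sizes = []

        def selector(X_tr, y_tr, fold_seed):
            seen_sizes.append(len(y_tr))
            cfg = sf.LOAConfig(population_size=4, iterations=2,
                               seed=int(fold_seed) % 2**31)
            best, _ = sf.loa_select(X_tr, y_tr, cfg,
                                    RFConfig(n_trees=10, seed=0), k=3)
            return best.mask.bits

        crossval(fx.X, fx.y, RFConfig(n_trees=10, seed=0), k=3, seed=0,
                 selector=selector)
        assert all(s == 20 for s in seen_sizes)  # 2/3 of 30: never the full n

        # on a fixed fold partition, shuffling the held-out labels cannot
        # change the mask, because selection consumes training folds only
        from sklearn.model_selection import StratifiedKFold
        tr, te = next(iter(StratifiedKFold(
            3, shuffle=True, random_state=0).split(fx.X, fx.y)))
        mask_before = selector(fx.X[tr], fx.y[tr], 0)
        y_mod = fx.y.copy()
        y_mod[te] = np.random.default_rng(7).permutation(y_mod[te])
        mask_after = selector(fx.X[tr], y_mod[tr], 0)
        np.testing.assert_array_equal(mask_before, mask_after)


class TestEvaluateAndAblation:
    def test_report_structure_and_ci_ordering(self):
        fx = sf.make_feature_fixture(20, 3, 3, 2, effect_size=3.0, seed=0)
        plan = split_dataset(fx.y, seed=0)
        model = train_rf(fx.X[plan.train_idx], fx.y[plan.train_idx],
                         RFConfig(n_trees=25, seed=0))
        prob = model.predict_proba(fx.X[plan.test_idx])
        pred = model.classes_[prob.argmax(axis=1)]
        rep = evaluate_predictions(fx.y[plan.test_idx], pred, prob,
                                   n_bootstrap=150, seed=0,
                                   classes=list(model.classes_))
        for m, est in rep.estimates.items():
            lo, hi = rep.cis[m]
            assert 0 <= lo <= est + 1e-12 and est - 1e-12 <= hi <= 1
        assert rep.confusion.sum() == len(plan.test_idx)

    def test_ablation_emits_five_named_variants(self):
        fx = sf.make_feature_fixture(20, 3, 3, 9, effect_size=4.0, seed=1)
        spans = {"sift": (0, 4), "deep": (4, 12)}
        table = run_ablation(fx.X, fx.y, spans,
                             rf_cfg=RFConfig(n_trees=20, seed=0),
                             loa_cfg=sf.LOAConfig(population_size=4,
                                                  iterations=2, seed=0),
                             seed=0, n_bootstrap=120)
        assert list(table) == ["sift->rf", "deep->rf", "sift+deep->rf",
                               "deep->lo-rf", "sift+deep->lo-rf"]

    def test_missing_spans_rejected(self):
        fx = sf.make_feature_fixture(10, 2, 2, 2, effect_size=2.0, seed=2)
        with pytest.raises(ValueError, match="spans"):
            run_ablation(fx.X, fx.y, {"sift": (0, 2)})
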