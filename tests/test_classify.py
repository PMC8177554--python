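"""CART, the four binary ensembles, one-vs-all ECOC, folds, tuning, CV."""

import numpy as np
import pytest

from gaitdnd import (
    CONDITIONS,
    ModelSpec,
    cross_validate,
    ecoc_one_vs_all,
    gaussian_feature_cohort,
    make_folds,
    paper_params,
    train_cart,
    train_ensemble,
    tune_hyperparameters,
)
from gaitdnd.classify import (
    METHODS,
    PARAM_RANGES,
    AdaBoostBinary,
    BaggingBinary,
)


class TestCart:
    def test_single_split_threshold_at_midpoint(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0]])
        y = np.array([0, 0, 1, 1])
        tree = train_cart(X, y, max_splits=1)
        thresholds = tree.tree_.threshold[tree.tree_.threshold > 0]
        assert thresholds == pytest.approx([5.0])
        assert np.array_equal(tree.predict(X), y)

    def test_min_leaf_equal_n_gives_single_leaf_majority(self):
        X = np.arange(10.0).reshape(-1, 1)
        y = np.array([0] * 6 + [1] * 4)
        tree = train_cart(X, y, min_leaf_size=10)
        assert tree.get_n_leaves() == 1
        assert np.all(tree.predict(X) == 0)

    def test_xor_solved_with_enough_splits(self, rng):
        X = rng.uniform(-1, 1, size=(200, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        tree = train_cart(X, y, max_splits=50)
        assert np.mean(tree.predict(X) != y) == 0.0

    def test_single_class_yields_trivial_tree(self):
        tree = train_cart(np.zeros((5, 2)), np.ones(5, dtype=int))
        assert tree.get_n_leaves() == 1


class TestBinaryEnsembles:
    def _separable(self, rng, n=60):
        X = np.vstack([rng.normal(-2, 0.5, (n // 2, 3)),
                       rng.normal(2, 0.5, (n // 2, 3))])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, y

    def test_bagging_without_bootstrap_equals_single_cart(self, rng):
        X, y = self._separable(rng)
        spec = ModelSpec(method="bagging", n_cycles=1, seed=0)
        bag = BaggingBinary(spec, bootstrap=False).fit(
            X, y, np.random.default_rng(0)
        )
        tree = train_cart(X, y, min_leaf_size=spec.min_leaf_size,
                          max_splits=spec.max_splits)
        np.testing.assert_allclose(
            bag.score(X), tree.predict_proba(X)[:, 1]
        )

    def test_adaboost_drives_training_error_to_zero_when_separable(self, rng):
        X, y = self._separable(rng)
        spec = ModelSpec(method="adaboost", n_cycles=5, seed=1)
        model = train_ensemble(X, y, spec)
        errors = model.staged_training_error(X, y)
        assert errors[-1] == 0.0

    def test_boosting_training_error_non_increasing_on_separable_data(
        self, rng
    ):
        X, y = self._separable(rng, n=100)
        spec = ModelSpec(method="adaboost", n_cycles=12, max_splits=2, seed=2)
        model = train_ensemble(X, y, spec)
        errors = model.staged_training_error(X, y)
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))

    def test_rusboost_beats_adaboost_minority_recall_under_imbalance(self):
        recalls = {"rusboost": [], "adaboost": []}
        for rep in range(100):
            rng = np.random.default_rng(3000 + rep)
            X = np.vstack([rng.normal(0.0, 1.0, (180, 4)),
                           rng.normal(0.9, 1.0, (20, 4))])
            y = np.array([0] * 180 + [1] * 20)
            perm = rng.permutation(200)
            Xtr, ytr = X[perm[:140]], y[perm[:140]]
            Xte, yte = X[perm[140:]], y[perm[140:]]
            for method in recalls:
                spec = ModelSpec(method=method, n_cycles=15, max_splits=4,
                                 seed=rep)
                model = train_ensemble(Xtr, ytr, spec)
                pred = (model.score(Xte) >= 0.5).astype(int)
                pos = yte == 1
                recalls[method].append(
                    np.mean(pred[pos] == 1) if pos.any() else np.nan
                )
        assert np.nanmean(recalls["rusboost"]) >= np.nanmean(
            recalls["adaboost"]
        )

    def test_subspace_uses_feature_subsets(self, rng):
        X, y = self._separable(rng)
        spec = ModelSpec(method="subspace", n_cycles=10,
                         subspace_fraction=0.34, seed=4)
        model = train_ensemble(X, y, spec)
        assert all(len(cols) == 1 for cols in model.subsets)

    def test_weight_reset_on_unlearnable_round(self, rng, caplog):
        # pure label noise: every round has error ~0.5
        X = rng.normal(size=(80, 2))
        y = rng.integers(0, 2, size=80)
        spec = ModelSpec(method="adaboost", n_cycles=5, max_splits=1,
                         min_leaf_size=40, seed=5)
        model = train_ensemble(X, y, spec)
        assert model.score(X).shape == (80,)


class TestEcoc:
    def test_separable_clusters_reach_full_resubstitution_accuracy(self):
        X, y = gaussian_feature_cohort(30, seed=6, separation=6.0)
        model = ecoc_one_vs_all(ModelSpec(method="tree", seed=0), X, y)
        assert set(model.learners) == set(CONDITIONS)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_tie_scores_predict_first_class_in_order(self):
        class Flat:
            def score(self, X):
                return np.full(len(X), 0.5)

        from gaitdnd.classify import TrainedModel

        model = TrainedModel(
            method="tree", class_order=CONDITIONS,
            learners={c: Flat() for c in CONDITIONS},
            spec=ModelSpec(method="tree"),
        )
        assert list(model.predict(np.zeros((3, 8)))) == ["CON"] * 3

    def test_binary_problem_reduces_to_two_complementary_learners(self, rng):
        X = np.vstack([rng.normal(-2, 0.3, (20, 2)),
                       rng.normal(2, 0.3, (20, 2))])
        y = np.array(["CON"] * 20 + ["ALS"] * 20)
        model = ecoc_one_vs_all(ModelSpec(method="tree", seed=0), X, y)
        assert len(model.learners) == 2
        scores = model.scores(X)
        np.testing.assert_allclose(scores[:, 0] + scores[:, 1], 1.0)

    def test_absent_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array(["CON"] * 10)
        with pytest.raises(ValueError, match="absent"):
            ecoc_one_vs_all(
                ModelSpec(method="tree"), X, y, class_order=("CON", "ALS")
            )


class TestFolds:
    def test_published_window_counts_give_balanced_folds(self, rng):
        y = np.array(
            ["CON"] * 160 + ["ALS"] * 96 + ["PD"] * 125 + ["HD"] * 166
        )
        assignment = make_folds(y, k=10, seed=7)
        sizes = [np.sum(assignment.folds == f) for f in range(10)]
        assert set(sizes) <= {54, 55}
        assert sum(sizes) == 547
        # per-fold class proportions within one sample of the overall
        for label, total in (("CON", 160), ("ALS", 96), ("PD", 125),
                             ("HD", 166)):
            per_fold = [
                np.sum((y == label) & (assignment.folds == f))
                for f in range(10)
            ]
            assert max(per_fold) - min(per_fold) <= 1

    def test_every_sample_in_exactly_one_test_fold(self, rng):
        y = rng.choice(CONDITIONS, size=200)
        assignment = make_folds(y, k=5, seed=8)
        seen = np.concatenate(
            [assignment.test_indices(f) for f in range(5)]
        )
        assert sorted(seen) == list(range(200))
        for f in range(5):
            assert not set(assignment.test_indices(f)) & set(
                assignment.train_indices(f)
            )

    def test_k_of_one_rejected(self):
        with pytest.raises(ValueError, match="k must be >= 2"):
            make_folds(np.array(["CON"] * 20), k=1)

    def test_class_smaller_than_k_rejected(self):
        y = np.array(["CON"] * 20 + ["ALS"] * 3)
        with pytest.raises(ValueError, match="ALS"):
            make_folds(y, k=5)

    def test_same_seed_same_assignment(self, rng):
        y = rng.choice(CONDITIONS, size=120)
        a = make_folds(y, k=4, seed=9)
        b = make_folds(y, k=4, seed=9)
        np.testing.assert_array_equal(a.folds, b.folds)


class TestCrossValidate:
    def test_deterministic_given_data_spec_seed(self):
        X, y = gaussian_feature_cohort(25, seed=10)
        spec = ModelSpec(method="bagging", n_cycles=10, seed=3)
        a = cross_validate((X, y), spec, k=5, seed=3)
        b = cross_validate((X, y), spec, k=5, seed=3)
        assert a.to_dict() == b.to_dict()

    def test_permuted_labels_give_chance_level_sensitivity(self):
        X, y = gaussian_feature_cohort(50, seed=11)
        y_perm = np.random.default_rng(11).permutation(y)
        spec = ModelSpec(method="tree", seed=0)
        result = cross_validate((X, y_perm), spec, k=5, seed=0)
        assert result.mean["sensitivity"] == pytest.approx(25.0, abs=5.0)

    def test_report_structure(self):
        X, y = gaussian_feature_cohort(15, seed=12, separation=4.0)
        spec = ModelSpec(method="subspace", n_cycles=5, seed=1)
        result = cross_validate((X, y), spec, k=3, seed=1)
        assert len(result.per_fold) == 3
        payload = result.to_dict()
        assert set(payload["mean"]) == {
            "accuracy", "sensitivity", "specificity", "f1", "kappa"
        }
        assert payload["spec"]["method"] == "subspace"


class TestTuning:
    def test_tuned_params_respect_declared_ranges(self):
        X, y = gaussian_feature_cohort(60, seed=13, separation=3.0)
        params = tune_hyperparameters(
            X, y, "adaboost", budget=10, seed=2, cycle_cap=15
        )
        for key, value in params.items():
            if key == "n_cycles":
                continue  # capped below its range for runtime
            low, high = PARAM_RANGES[key]
            assert low <= value <= high

    def test_same_seed_same_selection(self):
        X, y = gaussian_feature_cohort(60, seed=14, separation=3.0)
        kwargs = dict(budget=10, seed=4, cycle_cap=12)
        assert tune_hyperparameters(X, y, "tree", **kwargs) == \
            tune_hyperparameters(X, y, "tree", **kwargs)

    def test_small_budget_rejected(self):
        X, y = gaussian_feature_cohort(60, seed=15)
        with pytest.raises(ValueError, match="budget"):
            tune_hyperparameters(X, y, "tree", budget=5)

    def test_published_presets_are_complete_and_valid(self):
        for method in METHODS:
            for signal in ("vgrf", "stride", "stance", "swing"):
                params = paper_params(method, signal)
                ModelSpec(method=method, **params)  # must validate
        assert paper_params("adaboost", "vgrf")["n_cycles"] == 485
        assert paper_params("subspace", "vgrf")["subspace_fraction"] == 0.5
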