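import numpy as np
import pytest

from tpecascade import (
    CascadeConfig,
    CountVector,
    DegenerateTrainingError,
    UsageError,
    augment_features,
    fit_cascade,
    majority_vote,
)
from tpecascade.cascade import N_CLASSES

from conftest import TINY_TREES


def brute_force_vote(rows):
    """Independent oracle: explicit per-class accumulation, then scan for
    the first maximal class."""
    n_classes = len(rows[0])
    sums = [0.0] * n_classes
    for row in rows:
        for k in range(n_classes):
            sums[k] += row[k]
    best = 0
    for k in range(1, n_classes):
        if sums[k] > sums[best]:
            best = k
    return best


class TestMajorityVote:
    def test_two_row_arithmetic(self):
        assert majority_vote([(0.6, 0.4), (0.3, 0.7)]) == 1  # sums 0.9 vs 1.1

    def test_single_row_reduces_to_argmax(self):
        assert majority_vote([(0.2, 0.8)]) == 1

    def test_tie_breaks_to_smaller_class(self):
        assert majority_vote([(0.5, 0.5), (0.5, 0.5)]) == 0

    def test_empty_stack_rejected(self):
        with pytest.raises(UsageError):
            majority_vote([])

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n_learners = rng.integers(1, 13)
            raw = rng.random((n_learners, 2))
            rows = raw / raw.sum(axis=1, keepdims=True)
            assert majority_vote(rows) == brute_force_vote(rows.tolist())


@pytest.fixture(scope="module")
def wide_model(learnable_data):
    X, y, _ = learnable_data  # 334 x 10
    config = CascadeConfig(max_depth=1, k_inner=2, seed=3,
                           learner_params={f: {"n_estimators": 2} for f in TINY_TREES})
    return X, y, fit_cascade(X, y, CountVector(2, 5, 5, 0), config)


class TestAugmentation:
    def test_width_arithmetic_for_twelve_learners(self, wide_model):
        X, _, model = wide_model
        layer = model.layers[0]
        aug = augment_features(X, layer, mode="direct")
        assert aug.values.shape[1] == 10 + 12 * N_CLASSES == 34
        assert aug.original_width == 10 and aug.augment_width == 24

    def test_augment_block_is_probabilities(self, wide_model):
        X, _, model = wide_model
        aug = augment_features(X, model.layers[0], mode="direct")
        block = aug.values[:, aug.original_width:]
        assert np.all(block >= 0) and np.all(block <= 1)
        # each learner's 2-column slice sums to 1 per row
        for j in range(0, aug.augment_width, N_CLASSES):
            np.testing.assert_allclose(block[:, j:j + N_CLASSES].sum(axis=1), 1.0,
                                       atol=1e-9)

    def test_single_learner_width(self, separable_toy):
        X, y = separable_toy
        X3 = X[:, :3]
        config = CascadeConfig(max_depth=1, k_inner=2, seed=0, learner_params=TINY_TREES)
        model = fit_cascade(X3, y, CountVector(1, 0, 0, 0), config)
        aug = augment_features(X3, model.layers[0], mode="direct")
        assert aug.values.shape[1] == 5

    def test_out_of_fold_without_labels_is_usage_error(self, wide_model):
        X, _, model = wide_model
        with pytest.raises(UsageError):
            augment_features(X, model.layers[0], mode="out_of_fold")

    def test_out_of_fold_block_differs_from_direct(self, wide_model):
        X, y, model = wide_model
        direct = augment_features(X, model.layers[0], mode="direct")
        oof = augment_features(X, model.layers[0], mode="out_of_fold", y=y, seed=1)
        assert not np.allclose(direct.values, oof.values)


class TestFitCascade:
    def test_depth_growth_and_history(self, learnable_data, tiny_cascade_config):
        X, y, _ = learnable_data
        model = fit_cascade(X, y, CountVector(1, 1, 1, 1), tiny_cascade_config)
        assert model.depth >= 1
        assert model.history
        accs = [r.val_accuracy for r in model.history]
        # the retained depth scores the maximum recorded validation accuracy
        assert model.history[model.depth - 1].val_accuracy == max(accs)
        # discarded flags mark exactly the layers beyond the chosen depth
        assert all(r.discarded == (r.index > model.depth) for r in model.history)

    def test_stopping_rule(self, learnable_data, tiny_cascade_config):
        X, y, _ = learnable_data
        model = fit_cascade(X, y, CountVector(1, 1, 0, 0), tiny_cascade_config)
        accs = [r.val_accuracy for r in model.history]
        best = int(np.argmax(accs))
        # with patience 1, at most one non-improving layer was trained
        assert len(accs) <= best + 1 + tiny_cascade_config.patience
        if len(accs) > 1 and accs[1] < accs[0]:
            assert model.depth == 1

    def test_layers_share_composition_and_width_law(self, learnable_data):
        X, y, _ = learnable_data
        config = CascadeConfig(max_depth=3, patience=3, k_inner=2, seed=2,
                               learner_params=TINY_TREES)
        counts = CountVector(1, 1, 1, 0)
        model = fit_cascade(X, y, counts, config)
        for layer in model.layers:
            families = sorted(l.family for l in layer.learners)
            expected = sorted(
                f for f, c in zip(("RF", "ET", "ADA", "GBDT"), counts) for _ in range(c)
            )
            assert [f.value for f in families] == sorted(expected)
            if layer.index == 1:
                assert layer.input_width == X.shape[1]
            else:
                assert layer.input_width == X.shape[1] + counts.total * N_CLASSES

    def test_noise_labels_stay_near_majority_rate(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((400, 8))
        y = rng.integers(0, 2, size=400)
        config = CascadeConfig(max_depth=2, patience=1, k_inner=2, seed=9,
                               learner_params=TINY_TREES)
        model = fit_cascade(X, y, CountVector(1, 1, 0, 0), config)
        chosen_acc = model.history[model.depth - 1].val_accuracy
        majority = max(np.mean(y), 1 - np.mean(y))
        n_val = int(round(400 * config.holdout_fraction))
        sigma = np.sqrt(majority * (1 - majority) / n_val)
        assert abs(chosen_acc - majority) <= 3 * sigma

    def test_single_class_rejected(self, learnable_data, tiny_cascade_config):
        X, _, _ = learnable_data
        with pytest.raises(DegenerateTrainingError):
            fit_cascade(X, np.ones(len(X), dtype=int), CountVector(1, 0, 0, 0),
                        tiny_cascade_config)

    def test_too_few_samples_for_inner_folds(self, tiny_cascade_config):
        X = np.random.default_rng(0).standard_normal((4, 3))
        y = np.array([0, 1, 0, 1])
        config = CascadeConfig(k_inner=5, learner_params=TINY_TREES)
        with pytest.raises(Exception):
            fit_cascade(X, y, CountVector(1, 0, 0, 0), config)


class TestPredict:
    def test_degenerate_cascade_equals_single_rf(self, learnable_data):
        X, y, _ = learnable_data
        config = CascadeConfig(max_depth=1, k_inner=2, seed=4, learner_params=TINY_TREES)
        model = fit_cascade(X, y, CountVector(1, 0, 0, 0), config)
        assert model.depth == 1 and len(model.layers[0].learners) == 1
        rf = model.layers[0].learners[0]
        probe = X[:50]
        np.testing.assert_array_equal(
            model.predict(probe), np.argmax(rf.predict_proba(probe), axis=1)
        )

    def test_predict_consistent_with_proba(self, learnable_data, tiny_cascade_config):
        X, y, _ = learnable_data
        model = fit_cascade(X, y, CountVector(1, 1, 0, 0), tiny_cascade_config)
        scores = model.predict_proba(X[:40])
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(model.predict(X[:40]), np.argmax(scores, axis=1))

    def test_refit_same_seed_identical_predictions(self, learnable_data, tiny_cascade_config):
        X, y, _ = learnable_data
        m1 = fit_cascade(X, y, CountVector(1, 0, 1, 0), tiny_cascade_config)
        m2 = fit_cascade(X, y, CountVector(1, 0, 1, 0), tiny_cascade_config)
        probe = X[:60]
        np.testing.assert_array_equal(m1.predict(probe), m2.predict(probe))

    def test_width_mismatch_raises(self, learnable_data, tiny_cascade_config):
        X, y, _ = learnable_data
        model = fit_cascade(X, y, CountVector(1, 0, 0, 0), tiny_cascade_config)
        with pytest.raises(ValueError):
            model.predict(X[:, :4])


def test_cascade_does_not_degrade_its_first_layer(learnable_data):
    """Mean CV accuracy of the grown cascade stays within one percentage
    point of its own depth-1 version on learnable data, over 5 seeds."""
    from tpecascade.evaluation import cv_splits

    X, y, _ = learnable_data
    deep_accs, shallow_accs = [], []
    for seed in range(5):
        for tr, te in cv_splits(y, n_folds=3, n_repeats=1, seed=seed):
            deep = fit_cascade(X[tr], y[tr], CountVector(1, 1, 0, 0),
                               CascadeConfig(max_depth=3, patience=1, k_inner=2,
                                             seed=seed, learner_params=TINY_TREES))
            shallow = fit_cascade(X[tr], y[tr], CountVector(1, 1, 0, 0),
                                  CascadeConfig(max_depth=1, k_inner=2,
                                                seed=seed, learner_params=TINY_TREES))
            deep_accs.append(np.mean(deep.predict(X[te]) == y[te]))
            shallow_accs.append(np.mean(shallow.predict(X[te]) == y[te]))
    assert np.mean(deep_accs) >= np.mean(shallow_accs) - 0.01
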