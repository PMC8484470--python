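"""Min-max normalization, SVM training, and the 108-point grid search."""

import numpy as np
import pytest

from wbckit.classifier import (
    DEFAULT_CONFIG,
    GRID_C,
    GRID_NEUTROPHIL_WEIGHTS,
    KERNELS,
    SvmConfig,
    cross_validate_config,
    fit_norm,
    grid_configs,
    grid_search,
    load_model,
    predict,
    save_model,
    train,
)
from wbckit.synthetic import make_feature_dataset


@pytest.fixture(scope="module")
def separable():
    return make_feature_dataset(20, separation=10.0, seed=3)


class TestNormStats:
    def test_min_max_arithmetic(self):
        X = np.array([[0.0], [5.0], [10.0]])
        norm = fit_norm(X)
        np.testing.assert_allclose(norm.apply(X).ravel(), [0.0, 0.5, 1.0])

    def test_constant_feature_maps_to_zero(self):
        X = np.array([[3.0, 1.0], [3.0, 2.0]])
        out = fit_norm(X).apply(X)
        np.testing.assert_array_equal(out[:, 0], 0.0)

    def test_out_of_range_values_clamped(self):
        norm = fit_norm(np.array([[0.0], [10.0]]))
        out = norm.apply(np.array([[-5.0], [25.0]]))
        np.testing.assert_allclose(out.ravel(), [0.0, 1.0])

    def test_requires_two_vectors(self):
        with pytest.raises(ValueError):
            fit_norm(np.ones((1, 51)))


class TestTrainPredict:
    def test_default_config_trains_on_synthetic_features(self, separable):
        X, y = separable
        model = train(X, y, DEFAULT_CONFIG, seed=0)
        assert set(model.classes) == set(np.unique(y))

    def test_separable_clusters_reach_full_training_accuracy(self, separable):
        X, y = separable
        model = train(X, y, DEFAULT_CONFIG, seed=0)
        assert (predict(model, X) == y).mean() == 1.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 51))
        with pytest.raises(ValueError):
            train(X, ["lymphocyte"] * 10)

    def test_prediction_order_equivariance(self, separable):
        X, y = separable
        model = train(X, y, DEFAULT_CONFIG, seed=0)
        perm = np.random.default_rng(1).permutation(len(X))
        np.testing.assert_array_equal(predict(model, X)[perm], predict(model, X[perm]))

    def test_wrong_dimensionality_rejected(self, separable):
        X, y = separable
        model = train(X, y, DEFAULT_CONFIG, seed=0)
        with pytest.raises(ValueError):
            predict(model, np.zeros((2, 13)))

    def test_persistence_round_trip(self, separable, tmp_path):
        X, y = separable
        model = train(X, y, DEFAULT_CONFIG, seed=0)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(predict(model, X), predict(loaded, X))
        assert loaded.config == model.config
        assert loaded.fingerprint == model.fingerprint

    def test_holdout_accuracy_on_class_separated_features(self):
        X, y = make_feature_dataset(30, separation=8.0, seed=9)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(X))
        cut = int(0.7 * len(X))
        model = train(X[idx[:cut]], y[idx[:cut]], DEFAULT_CONFIG, seed=0)
        acc = (predict(model, X[idx[cut:]]) == y[idx[cut:]]).mean()
        assert acc >= 0.95


class TestGridSearch:
    def test_grid_has_108_configurations(self):
        configs = grid_configs()
        assert len(configs) == 108
        assert len(set(configs)) == 108
        assert {c.kernel for c in configs} == set(KERNELS)
        assert {c.C for c in configs} == set(float(c) for c in GRID_C)
        assert {c.neutrophil_weight for c in configs} == set(
            float(w) for w in GRID_NEUTROPHIL_WEIGHTS
        )

    def test_separable_dataset_scores_high_everywhere(self, separable):
        X, y = separable
        best, table = grid_search(X, y, seed=0)
        assert len(table) == 108
        assert (table["mean_accuracy"] >= 0.9).all()
        best_row = table.sort_values("mean_accuracy", ascending=False).iloc[0]
        assert best_row["mean_accuracy"] == table["mean_accuracy"].max()

    def test_tie_break_prefers_small_c_small_weight(self, separable):
        X, y = separable
        best, table = grid_search(X, y, seed=0)
        top = table[table["mean_accuracy"] == table["mean_accuracy"].max()]
        assert best.C == top["C"].min()

    def test_seeded_search_is_reproducible(self, separable):
        X, y = separable
        best1, table1 = grid_search(X, y, seed=7)
        best2, table2 = grid_search(X, y, seed=7)
        assert best1 == best2
        assert table1.equals(table2)

    def test_too_few_samples_per_class_rejected(self):
        X, y = make_feature_dataset(3, separation=5.0, seed=0)
        with pytest.raises(ValueError):
            grid_search(X, y, seed=0)

    def test_fold_normalization_uses_training_fold_only(self, separable):
        X, y = separable
        _, details = cross_validate_config(
            X, y, DEFAULT_CONFIG, seed=0, return_details=True
        )
        for train_idx, _, norm in details:
            np.testing.assert_array_equal(norm.minimum, X[train_idx].min(axis=0))
            np.testing.assert_array_equal(norm.maximum, X[train_idx].max(axis=0))


class TestClassWeight:
    def test_raising_neutrophil_weight_never_hurts_neutrophil_sensitivity(self):
        # imbalanced, overlapping clusters: few neutrophils, modest separation
        from wbckit.synthetic import WBC_CLASSES

        deltas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X, y = make_feature_dataset(40, separation=1.5, seed=seed)
            keep = np.ones(len(y), bool)
            neut = np.where(y == "neutrophil")[0]
            keep[neut[8:]] = False  # under-represent neutrophils
            Xi, yi = X[keep], y[keep]
            idx = rng.permutation(len(yi))
            cut = int(0.7 * len(yi))
            tr, te = idx[:cut], idx[cut:]
            sens = {}
            for w in (1.0, 20.0):
                cfg = SvmConfig(kernel="rbf", C=4.0, neutrophil_weight=w)
                model = train(Xi[tr], yi[tr], cfg, seed=0)
                pred = predict(model, Xi[te])
                mask = yi[te] == "neutrophil"
                sens[w] = (pred[mask] == "neutrophil").mean() if mask.any() else 1.0
            deltas.append(sens[20.0] - sens[1.0])
        assert np.mean(deltas) >= -0.05  # monotone within sampling noise

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SvmConfig(kernel="sigmoid")
        with pytest.raises(ValueError):
            SvmConfig(C=-1)
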