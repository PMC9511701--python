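"""Base-learner zoo: grids, training contracts and deterministic prediction."""

import numpy as np
import pytest

from synerstack.learners import (DEFAULT_ARCHITECTURES, ModelConfig,
                                 enumerate_grid, grid_search, predict,
                                 train_model, train_net, train_tabular)


def toy_regression(n=120, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 5))
    y = 2 * X[:, 0] - X[:, 1] + 0.1 * rng.normal(size=n)
    return X, y


def toy_classification(n=200, seed=0, margin=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    X[y == 1] += margin / np.sqrt(2)
    X[y == 0] -= margin / np.sqrt(2)
    return X, y


class TestGrid:
    def test_cartesian_product_sizes(self):
        assert len(enumerate_grid({"a": [1, 2], "b": [1, 2, 3]})) == 6
        assert len(enumerate_grid({"a": [7]})) == 1

    def test_default_architecture_axis_has_twelve_entries(self):
        grid = enumerate_grid({"dataset": list("abcd"),
                               "architecture": list(DEFAULT_ARCHITECTURES),
                               "dropout": [0.0, 0.25, 0.5, 0.75]})
        assert len(grid) == 192

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            enumerate_grid({"a": []})

    def test_single_candidate_grid_returns_it(self):
        X, y = toy_regression()
        best, results = grid_search([{"n_neighbors": 3}], "k_nearest_neighbors",
                                    "regression", X, y,
                                    subsample_fraction=0.5, seed=0)
        assert best.hyperparameters == {"n_neighbors": 3}
        assert len(results) == 1

    def test_knn_exact_match_dominates_on_duplicated_points(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(100, 3))
        labels = (base[:, 0] > 0).astype(int)
        X = np.vstack([base, base])  # every point duplicated with its label
        y = np.concatenate([labels, labels])
        best, _ = grid_search([{"n_neighbors": 1}, {"n_neighbors": 51}],
                              "k_nearest_neighbors", "classification", X, y,
                              subsample_fraction=1.0, seed=0)
        assert best.hyperparameters["n_neighbors"] == 1

    def test_grid_search_is_deterministic(self):
        X, y = toy_regression()
        _, r1 = grid_search([{"n_neighbors": k} for k in (1, 3, 5)],
                            "k_nearest_neighbors", "regression", X, y,
                            subsample_fraction=0.5, seed=4)
        _, r2 = grid_search([{"n_neighbors": k} for k in (1, 3, 5)],
                            "k_nearest_neighbors", "regression", X, y,
                            subsample_fraction=0.5, seed=4)
        assert r1.equals(r2)

    def test_too_small_subsample_suggests_larger_fraction(self):
        X, y = toy_regression(n=40)
        with pytest.raises(ValueError, match="subsample_fraction"):
            grid_search([{"n_neighbors": 1}], "k_nearest_neighbors",
                        "regression", X, y, subsample_fraction=0.05)


class TestNets:
    def test_architecture_defines_layer_widths(self):
        X, y = toy_regression(n=40)
        model = train_net(ModelConfig("feedforward_net", "regression",
                                      {"architecture": [10, 10, 10], "epochs": 1}),
                          X, y)
        assert model.estimator.layer_widths == [5, 10, 10, 10, 1]

    def test_separable_classification_reaches_high_accuracy(self):
        X, y = toy_classification()
        config = ModelConfig("feedforward_net", "classification",
                             {"architecture": [16], "learning_rate": 1e-2,
                              "epochs": 60})
        model = train_net(config, X, y, seed=0)
        acc = np.mean((predict(model, X) >= 0.5) == y)
        assert acc > 0.95
        # sanity: the generator's separating direction alone does as well
        assert np.mean((X[:, 0] + X[:, 1] > 0) == y) > 0.95

    def test_dropout_layers_follow_architecture(self):
        X, y = toy_regression(n=30)
        config = ModelConfig("feedforward_net", "regression",
                             {"architecture": [8, 8, 8], "dropout": 0.5,
                              "epochs": 2})
        model = train_net(config, X, y)
        assert model.estimator.dropout == 0.5
        assert len(model.estimator.layer_widths) == 5  # 3 hidden + in/out

    def test_loss_decreases_on_training_data(self):
        X, y = toy_regression()
        config = ModelConfig("feedforward_net", "regression",
                             {"architecture": [16], "learning_rate": 1e-2,
                              "epochs": 30})
        curve = train_net(config, X, y).loss_curve
        assert curve[-1] <= curve[0]


class TestTabular:
    def test_xgboost_accepts_printed_hyperparameters(self):
        X, y = toy_classification()
        config = ModelConfig("gradient_boosted_trees", "classification",
                             {"alpha": 0.25, "max_depth": 6, "n_estimators": 100})
        model = train_tabular(config, X, y)
        scores = predict(model, X)
        assert scores.min() >= 0 and scores.max() <= 1

    def test_knn_k1_memorizes_training_labels(self):
        X, y = toy_classification(n=60)
        model = train_tabular(ModelConfig("k_nearest_neighbors", "classification",
                                          {"n_neighbors": 1}), X, y)
        assert np.array_equal((predict(model, X) >= 0.5).astype(int), y)

    def test_random_forest_constant_target(self):
        X, _ = toy_regression(n=50)
        model = train_tabular(ModelConfig("random_forest", "regression",
                                          {"n_estimators": 20}), X,
                              np.full(50, 3.5))
        np.testing.assert_allclose(predict(model, X), 3.5)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ModelConfig("boosted_ferns", "regression")


class TestPredictContract:
    def test_margin_models_emit_probability_like_scores(self):
        X, y = toy_classification()
        for fam in ("support_vector_machine", "linear_sgd"):
            model = train_model(ModelConfig(fam, "classification"), X, y)
            s = predict(model, X)
            assert s.min() >= 0 and s.max() <= 1

    def test_identical_rows_get_identical_predictions(self):
        X, y = toy_regression()
        model = train_model(ModelConfig("random_forest", "regression",
                                        {"n_estimators": 30}), X, y)
        X2 = np.vstack([X[:1], X[:1]])
        p = predict(model, X2)
        assert p[0] == p[1]

    def test_overfit_tree_ensemble_correlates_on_noiseless_target(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 4))
        y = X[:, 0] ** 2 + X[:, 1]
        model = train_model(ModelConfig("extremely_randomized_trees", "regression",
                                        {"n_estimators": 200}), X, y)
        assert np.corrcoef(predict(model, X), y)[0, 1] > 0.99

    def test_width_mismatch_rejected(self):
        X, y = toy_regression()
        model = train_model(ModelConfig("random_forest", "regression",
                                        {"n_estimators": 10}), X, y)
        with pytest.raises(ValueError, match="width"):
            predict(model, X[:, :3])

    def test_net_training_reproducible_under_seed(self):
        X, y = toy_regression(n=60)
        config = ModelConfig("feedforward_net", "regression",
                             {"architecture": [8], "epochs": 10,
                              "learning_rate": 1e-3})
        p1 = predict(train_net(config, X, y, seed=9), X)
        p2 = predict(train_net(config, X, y, seed=9), X)
        np.testing.assert_allclose(p1, p2, atol=1e-6)
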