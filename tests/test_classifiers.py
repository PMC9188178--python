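import numpy as np
import pytest

from seedscreen.classifiers import (
    EvalReport,
    SVMGridConfig,
    evaluate_model,
    grid_search_svm,
    split_dataset,
    train_classifier,
)


def _blobs(n_per_class=60, sep=6.0, dim=2, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n_per_class, dim))
    b = rng.normal(sep, 1, (n_per_class, dim))
    X = np.vstack([a, b])
    y = np.concatenate([np.ones(n_per_class, dtype=int), np.zeros(n_per_class, dtype=int)])
    return X, y


class TestSplitDataset:
    def test_single_stratum_8_rows(self):
        split = split_dataset(np.zeros(8), seed=0)
        assert len(split.train_idx) == 6 and len(split.test_idx) == 2

    def test_study_scale_rounding(self):
        # 315 + 315 rows: per-stratum test = round(315/4) = 79 -> 472 train, 158 test
        strata = np.array(["a"] * 315 + ["b"] * 315)
        split = split_dataset(strata, seed=1)
        assert len(split.test_idx) == 158
        assert len(split.train_idx) == 472
        for s in "ab":
            assert (strata[split.test_idx] == s).sum() == 79

    def test_deterministic(self):
        strata = np.repeat(np.arange(3), 20)
        s1 = split_dataset(strata, seed=42)
        s2 = split_dataset(strata, seed=42)
        np.testing.assert_array_equal(s1.train_idx, s2.train_idx)
        np.testing.assert_array_equal(s1.test_idx, s2.test_idx)

    def test_disjoint_and_complete(self):
        strata = np.repeat(np.arange(4), 11)
        split = split_dataset(strata, seed=3)
        union = np.sort(np.concatenate([split.train_idx, split.test_idx]))
        np.testing.assert_array_equal(union, np.arange(44))

    def test_singleton_stratum_rejected(self):
        with pytest.raises(ValueError, match="stratum"):
            split_dataset(np.array(["a", "a", "b"]))


class TestSVMGrid:
    def test_default_grid_is_101_by_101(self):
        cfg = SVMGridConfig()
        assert len(cfg.exponents()) == 101
        assert cfg.exponents()[0] == -10.0
        assert cfg.exponents()[-1] == pytest.approx(10.0)
        np.testing.assert_allclose(np.diff(cfg.exponents()), 0.2)

    def test_values_are_base_powers(self):
        cfg = SVMGridConfig(lo=-2, hi=2, step=1.0)
        np.testing.assert_allclose(cfg.values(), [0.25, 0.5, 1.0, 2.0, 4.0])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SVMGridConfig(lo=5, hi=-5)
        with pytest.raises(ValueError):
            SVMGridConfig(step=0)
        with pytest.raises(ValueError):
            SVMGridConfig(folds=1)

    def test_separable_blobs_perfect_cv(self):
        X, y = _blobs(sep=8.0)
        c, g, surface = grid_search_svm(X, y, SVMGridConfig(lo=-4, hi=4, step=2.0), seed=0)
        assert surface.max() == pytest.approx(1.0)
        assert surface.shape == (5, 5)

    def test_permutation_null_cv_accuracy(self):
        # best-of-grid CV accuracy on label-permuted data stays near chance
        rng = np.random.default_rng(7)
        best = []
        for rep in range(20):
            X = rng.normal(size=(200, 5))
            y = np.array([1] * 100 + [0] * 100)
            rng.shuffle(y)
            _, _, surface = grid_search_svm(
                X, y, SVMGridConfig(lo=-2, hi=2, step=2.0, folds=5), seed=rep
            )
            best.append(surface.max())
        assert 0.4 <= np.mean(best) <= 0.7
        assert all(0.35 <= b <= 0.75 for b in best)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError, match="class"):
            grid_search_svm(X, np.ones(20, dtype=int))


class TestTrainClassifier:
    @pytest.mark.parametrize("algorithm", ["rf", "svm", "mlp"])
    def test_separable_data_perfect(self, algorithm):
        X, y = _blobs(sep=8.0)
        Xt, yt = _blobs(sep=8.0, seed=99)
        config = {"n_estimators": 50} if algorithm == "rf" else (
            {"c": 1.0, "g": 0.5} if algorithm == "svm" else {"solver": "lbfgs"}
        )
        model = train_classifier(algorithm, X, y, config=config, seed=0)
        assert (model.predict(Xt) == yt).mean() == 1.0

    def test_mlp_solves_xor(self):
        rng = np.random.default_rng(0)
        corners = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        labels = np.array([0, 1, 1, 0])
        X = np.vstack([corners + rng.normal(0, 0.05, (4, 2)) for _ in range(50)])
        y = np.tile(labels, 50)
        accs = []
        for seed in range(3):
            model = train_classifier(
                "mlp", X, y, config={"hidden_units": 8, "solver": "lbfgs", "max_iter": 2000}, seed=seed
            )
            accs.append((model.predict(X) == y).mean())
        assert max(accs) == 1.0

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="class"):
            train_classifier("rf", X, np.ones(10, dtype=int))

    def test_nan_features_rejected(self):
        X, y = _blobs()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train_classifier("svm", X, y, config={"c": 1.0, "g": 0.1})

    def test_unknown_algorithm_rejected(self):
        X, y = _blobs()
        with pytest.raises(ValueError, match="algorithm"):
            train_classifier("xgboost", X, y)

    def test_schema_width_enforced(self):
        X, y = _blobs(dim=3)
        model = train_classifier("svm", X, y, config={"c": 1.0, "g": 0.1})
        with pytest.raises(ValueError, match="schema"):
            model.predict(np.zeros((2, 5)))

    def test_mlp_architecture(self):
        X, y = _blobs()
        model = train_classifier("mlp", X, y, config={"solver": "lbfgs"}, seed=0)
        mlp = model.pipeline.named_steps["mlp"]
        assert mlp.hidden_layer_sizes == (32,)
        assert mlp.activation == "logistic"
        assert mlp.n_outputs_ == 1  # two-class softmax == logistic output

    def test_save_load_round_trip(self, tmp_path):
        X, y = _blobs()
        model = train_classifier("svm", X, y, config={"c": 1.0, "g": 0.1}, seed=0)
        model.save(tmp_path / "model")
        from seedscreen.classifiers import TrainedModel

        back = TrainedModel.load(tmp_path / "model")
        np.testing.assert_array_equal(back.predict(X), model.predict(X))
        assert back.schema == model.schema


class TestEvaluateModel:
    def test_separable_perfect_report(self):
        X, y = _blobs(sep=8.0)
        report = evaluate_model(
            "svm", X, y, runs=3, seed=0, config={"c": 1.0, "g": 0.5}
        )
        assert report.accuracy == 1.0
        assert report.confusion[0, 1] == 0 and report.confusion[1, 0] == 0

    def test_confusion_row_sums_match_truth(self):
        X, y = _blobs(sep=1.0, n_per_class=40)
        report = evaluate_model("svm", X, y, runs=4, seed=1, config={"c": 1.0, "g": 0.5})
        # per run, 10 test rows per class -> pooled 40 per class
        assert report.confusion[0].sum() == 40
        assert report.confusion[1].sum() == 40

    def test_chance_level_on_pure_noise(self):
        rng = np.random.default_rng(5)
        accs = []
        for rep in range(5):
            X = rng.normal(size=(200, 10))
            y = np.array([1] * 100 + [0] * 100)
            report = evaluate_model(
                "svm", X, y, runs=4, seed=rep, config={"c": 1.0, "g": 0.1}
            )
            accs.extend(report.run_accuracies)
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_runs_one_equals_manual_composition(self):
        X, y = _blobs(sep=2.0)
        report = evaluate_model("svm", X, y, runs=1, seed=9, config={"c": 1.0, "g": 0.5})
        split = split_dataset(y, seed=9)
        model = train_classifier(
            "svm", X[split.train_idx], y[split.train_idx], config={"c": 1.0, "g": 0.5}, seed=9
        )
        manual = (model.predict(X[split.test_idx]) == y[split.test_idx]).mean()
        assert report.run_accuracies == [pytest.approx(manual)]

    def test_ten_runs_reported(self):
        X, y = _blobs(sep=8.0, n_per_class=30)
        report = evaluate_model("svm", X, y, seed=0, config={"c": 1.0, "g": 0.5})
        assert len(report.run_accuracies) == 10

    def test_feature_permutation_invariance(self):
        X, y = _blobs(sep=2.0, dim=4)
        perm = [2, 0, 3, 1]
        r1 = evaluate_model("svm", X, y, runs=2, seed=3, config={"c": 1.0, "g": 0.25})
        r2 = evaluate_model("svm", X[:, perm], y, runs=2, seed=3, config={"c": 1.0, "g": 0.25})
        assert r1.run_accuracies == pytest.approx(r2.run_accuracies)

    def test_invalid_runs(self):
        X, y = _blobs()
        with pytest.raises(ValueError, match="runs"):
            evaluate_model("svm", X, y, runs=0)


class TestEvalReport:
    def test_accuracy_definitions(self):
        rep = EvalReport(confusion=[[40, 10], [5, 45]], run_accuracies=[0.8, 0.9])
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.pooled_accuracy == pytest.approx(85 / 100)

    def test_negative_confusion_rejected(self):
        with pytest.raises(ValueError):
            EvalReport(confusion=[[1, -1], [0, 2]], run_accuracies=[0.5])
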