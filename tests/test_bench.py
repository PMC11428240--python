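import numpy as np
import pandas as pd
import pytest

from bovitherm import bench, featuresets
from bovitherm.bench import SplitConfig, metrics, split_train_test


class TestSplit:
    def test_paper_arithmetic(self):
        X = np.zeros((3005, 2))
        y = np.zeros(3005)
        X_tr, X_te, y_tr, y_te = split_train_test(X, y, SplitConfig(seed=0))
        assert len(y_te) == 601
        assert len(y_tr) == 2404

    def test_deterministic(self):
        X = np.arange(100).reshape(-1, 1)
        y = np.arange(100, dtype=float)
        a = split_train_test(X, y, SplitConfig(seed=5))
        b = split_train_test(X, y, SplitConfig(seed=5))
        np.testing.assert_array_equal(a[3], b[3])

    def test_disjoint_partitions(self):
        X = np.arange(50).reshape(-1, 1)
        y = np.arange(50, dtype=float)
        X_tr, X_te, _, _ = split_train_test(X, y, SplitConfig(seed=1))
        assert set(X_tr.ravel()) | set(X_te.ravel()) == set(range(50))
        assert not set(X_tr.ravel()) & set(X_te.ravel())

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitConfig(test_fraction=0.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="n_folds"):
            split_train_test(np.zeros((3, 1)), np.zeros(3), SplitConfig())


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([38.0, 38.5, 39.0])
        assert metrics(y, y) == (1.0, 0.0, 0.0)

    def test_hand_values(self):
        r2, mae, rmse = metrics([38.0, 40.0], [39.0, 39.0])
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert mae == pytest.approx(1.0)
        assert rmse == pytest.approx(1.0)

    def test_mean_predictor_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        r2, _, _ = metrics(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_r2_nan(self, caplog):
        r2, mae, rmse = metrics([2.0, 2.0], [1.0, 3.0])
        assert np.isnan(r2)
        assert mae == 1.0

    def test_rmse_ge_mae(self, rng):
        for _ in range(20):
            y = rng.normal(size=30)
            p = rng.normal(size=30)
            _, mae, rmse = metrics(y, p)
            assert rmse >= mae >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics([1.0], [1.0, 2.0])


class TestFamilies:
    def test_default_params_inside_ranges(self):
        for family in bench.FAMILIES:
            params = bench.default_params(family)
            bench.validate_params(family, params)  # should not raise

    def test_out_of_range_rejected_with_bound(self):
        params = bench.default_params("XGBoost")
        params["n_estimators"] = 1500
        with pytest.raises(ValueError, match=r"\[100, 1000\]"):
            bench.build_estimator("XGBoost", params)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown model family"):
            bench.family_space("SVM")

    def test_ann_architectures_restricted(self):
        space = bench.family_space("ANN")
        dim = next(d for d in space.dims if d.name == "hidden_layer_sizes")
        assert dim.options == ((100,), (100, 50))

    def test_en_recovers_linear_truth(self, rng):
        # near-unregularized elastic net on noiseless linear data
        X = rng.normal(size=(200, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 3.0
        params = {"alpha": 0.0001, "l1_ratio": 0.5}
        est = bench.build_estimator("EN", params)
        est.fit(X, y)
        r2, _, _ = metrics(y, est.predict(X))
        assert r2 > 0.999

    def test_all_families_fit_predict(self, rng):
        X = rng.normal(size=(80, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 80)
        for family in bench.FAMILIES:
            params = bench.default_params(family)
            # shrink iteration counts for speed
            for key in ("n_estimators", "num_iteration", "iterations", "max_iter"):
                if key in params:
                    params[key] = max(
                        100, 200 if key == "max_iter" else 100
                    )
            est = bench.build_estimator(family, params, seed=0)
            bench._fit(est, X, y)
            assert est.predict(X).shape == (80,)


class TestTrainModel:
    def test_cv_deterministic(self, rng):
        X = rng.normal(size=(120, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 120)
        params = bench.default_params("CatBoost")
        params["iterations"] = 100
        cfg = SplitConfig(seed=3)
        a = bench.cv_rmse("CatBoost", params, X, y, cfg)
        b = bench.cv_rmse("CatBoost", params, X, y, cfg)
        assert a == b

    def test_train_model_returns_cv_result(self, rng):
        X = pd.DataFrame(rng.normal(size=(120, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(0, 0.1, 120)
        params = {"alpha": 0.001, "l1_ratio": 0.5}
        model, result = bench.train_model("EN", params, X, y, SplitConfig(seed=0))
        assert result.split == "cv"
        assert result.rmse > 0
        assert model.predict(X.to_numpy(float)).shape == (120,)

    def test_cv_folds_partition_training_set(self):
        from sklearn.model_selection import KFold

        cfg = SplitConfig(seed=9)
        kf = KFold(n_splits=cfg.n_folds, shuffle=cfg.shuffle, random_state=cfg.seed)
        seen = []
        for _, te in kf.split(np.zeros((103, 1))):
            seen.extend(te.tolist())
        assert sorted(seen) == list(range(103))


@pytest.fixture(scope="module")
def mini_results(featured_small, registry):
    sub = [s for s in registry if s.name in ("ENV", "IRTave_TK")]
    return bench.benchmark(
        sub, featured_small, families=("EN", "RF"),
        config=SplitConfig(seed=42),
    )


class TestBenchmark:
    def test_result_shape(self, mini_results):
        # 2 sets x 2 families x 2 splits
        assert len(mini_results) == 8
        assert set(mini_results["split"]) == {"train", "test"}

    def test_aggregate(self, mini_results):
        agg = bench.aggregate_by_set(mini_results)
        assert set(agg["feature_set"]) == {"ENV", "IRTave_TK"}
        assert (agg["n_families"] == 2).all()
        assert (agg["rmse_sd"] >= 0).all()

    def test_aggregate_identical_results_zero_sd(self):
        rows = [
            {"feature_set": "ENV", "group": "environment", "model_family": f,
             "split": "test", "r2": 0.5, "mae": 0.2, "rmse": 0.3}
            for f in bench.FAMILIES
        ]
        agg = bench.aggregate_by_set(pd.DataFrame(rows))
        assert agg["r2_sd"].iloc[0] == 0.0

    def test_r2_ceiling_not_exceeded(self, mini_results, small_cohort, small_config):
        from bovitherm import synthetic

        _, truth = small_cohort
        ceiling = synthetic.theoretical_r2_ceiling(truth, small_config)
        test_rows = mini_results[mini_results.split == "test"]
        assert (test_rows["r2"] <= ceiling + 0.1).all()


class TestPairedT:
    def test_matches_scipy_example(self):
        a = [0.50, 0.52, 0.47, 0.49, 0.51, 0.48]
        b = [0.55, 0.56, 0.50, 0.53, 0.55, 0.51]
        t, df, p = bench.paired_t(a, b)
        assert df == 5
        assert t < 0  # b systematically larger
        assert 0 < p < 0.05

    def test_rejects_short_input(self):
        with pytest.raises(ValueError):
            bench.paired_t([1.0], [2.0])
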