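import numpy as np
import pandas as pd
import pytest

from conftest import make_feature_frame
from gaitdemog import (ModelConfig, load_predictor, predict, rfe_select,
                       save_predictor, split_dataset, train_predictor,
                       train_stacking)
from gaitdemog.errors import ConfigurationError, DataError
from gaitdemog.models import encode_sex


class TestSplit:
    def test_subject_level_exact_fraction(self):
        df = make_feature_frame(n_subjects=100, windows_per_subject=3)
        train, test = split_dataset(df, 0.7, by_subject=True, seed=0)
        assert train["subject_id"].nunique() == 70
        assert test["subject_id"].nunique() == 30

    def test_subject_disjointness(self):
        df = make_feature_frame(n_subjects=30)
        train, test = split_dataset(df, 0.7, by_subject=True, seed=1)
        assert not set(train["subject_id"]) & set(test["subject_id"])
        assert len(train) + len(test) == len(df)

    def test_same_seed_same_split(self):
        df = make_feature_frame(n_subjects=40)
        t1, _ = split_dataset(df, 0.7, seed=9)
        t2, _ = split_dataset(df, 0.7, seed=9)
        assert t1.equals(t2)

    def test_invalid_fraction_rejected(self):
        df = make_feature_frame(n_subjects=10)
        with pytest.raises(ConfigurationError):
            split_dataset(df, 1.5)


class TestRFE:
    def _planted(self, seed, n=500, p=100, informative=5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:informative] = [2.0, -1.5, 1.0, 0.8, -0.6][:informative]
        logits = X @ beta
        y = rng.random(n) < 1 / (1 + np.exp(-logits))
        df = pd.DataFrame(X, columns=[f"f{i:03d}" for i in range(p)])
        df["sex"] = np.where(y, "male", "female")
        df["subject_id"] = [f"S{i}" for i in range(n)]
        df["age"] = 30
        df["position"] = "center"
        df["start_time"] = 0.0
        return df

    def test_recovers_planted_linear_signal(self):
        df = self._planted(seed=7)
        selected = rfe_select(df, "sex", n_keep=30, seed=7)
        assert len(selected) == 30
        assert all(f"f{i:03d}" in selected for i in range(5))

    def test_trivial_when_nothing_to_drop(self):
        df = self._planted(seed=0, p=20)
        assert rfe_select(df, "sex", n_keep=30, seed=0) == \
            [f"f{i:03d}" for i in range(20)]

    def test_deterministic(self):
        df = self._planted(seed=3)
        assert rfe_select(df, "sex", n_keep=30, seed=1) == \
            rfe_select(df, "sex", n_keep=30, seed=1)

    def test_age_task_uses_linear_regressor_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 50))
        age = 40 + 10 * X[:, 0] - 8 * X[:, 1] + rng.normal(0, 1, 400)
        df = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(50)])
        df["sex"] = "male"
        df["age"] = age
        df["subject_id"] = [f"S{i}" for i in range(400)]
        df["position"] = "center"
        df["start_time"] = 0.0
        selected = rfe_select(df, "age", n_keep=10, seed=2)
        assert "f00" in selected and "f01" in selected


class TestTrainPredict:
    def test_separable_classes_fit_perfectly(self):
        df = make_feature_frame(n_subjects=30, sex_effect=8.0, seed=1)
        pred = train_predictor(df, ModelConfig("svc", "sex", seed=0))
        labels, scores = predict(pred, df)
        assert (labels == encode_sex(df["sex"])).mean() == 1.0
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_distance_weighted_knn_memorizes_training_targets(self):
        df = make_feature_frame(n_subjects=20, seed=2)
        pred = train_predictor(df, ModelConfig("knn", "age", seed=0))
        yhat = predict(pred, df)
        np.testing.assert_allclose(yhat, df["age"].to_numpy(float), atol=1e-9)

    def test_single_class_labels_rejected(self):
        df = make_feature_frame(n_subjects=10)
        df["sex"] = "male"
        with pytest.raises(DataError):
            train_predictor(df, ModelConfig("lr", "sex"))

    def test_missing_feature_column_named(self):
        df = make_feature_frame(n_subjects=10)
        pred = train_predictor(df, ModelConfig("lr", "sex", seed=0))
        with pytest.raises(DataError, match="f00"):
            predict(pred, df.drop(columns=["f00"]))

    def test_column_order_irrelevant(self):
        df = make_feature_frame(n_subjects=16, seed=4)
        pred = train_predictor(df, ModelConfig("rf", "sex", seed=0))
        labels1, _ = predict(pred, df)
        shuffled = df[list(df.columns[::-1])]
        labels2, _ = predict(pred, shuffled)
        np.testing.assert_array_equal(labels1, labels2)

    def test_serialization_round_trip(self, tmp_path):
        df = make_feature_frame(n_subjects=16, seed=5)
        pred = train_predictor(df, ModelConfig("lightgbm", "sex", seed=0))
        path = tmp_path / "model.joblib"
        save_predictor(pred, path)
        back = load_predictor(path)
        l1, s1 = predict(pred, df)
        l2, s2 = predict(back, df)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(s1, s2)


class TestStacking:
    def test_meta_input_width_with_passthrough(self):
        df = make_feature_frame(n_subjects=40, n_features=30, seed=6)
        pred = train_stacking(df, seed=0)
        stack = pred.pipeline.named_steps["model"]
        assert stack.final_estimator_.n_features_in_ == 33

    def test_meta_input_width_without_passthrough(self):
        df = make_feature_frame(n_subjects=40, n_features=30, seed=6)
        pred = train_stacking(df, passthrough=False, seed=0)
        stack = pred.pipeline.named_steps["model"]
        assert stack.final_estimator_.n_features_in_ == 3

    def test_deterministic_under_seed(self):
        df = make_feature_frame(n_subjects=30, seed=7)
        p1 = train_stacking(df, seed=3)
        p2 = train_stacking(df, seed=3)
        _, s1 = predict(p1, df)
        _, s2 = predict(p2, df)
        np.testing.assert_array_equal(s1, s2)

    def test_learns_separable_cohort(self):
        df = make_feature_frame(n_subjects=60, sex_effect=4.0, seed=8)
        train, test = split_dataset(df, 0.7, seed=8)
        pred = train_stacking(train, seed=8)
        labels, _ = predict(pred, test)
        assert (labels == encode_sex(test["sex"])).mean() > 0.9

    def test_fold_count_validated(self):
        df = make_feature_frame(n_subjects=20)
        with pytest.raises(ConfigurationError):
            train_stacking(df, n_folds=1)
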