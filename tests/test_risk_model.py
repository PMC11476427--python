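"""Encoding, imbalance handling, gradient boosting and evaluation."""

import numpy as np
import pandas as pd
import pytest

from carotidrisk import risk_model as rm
from carotidrisk import synth_data as sd


@pytest.fixture(scope="module")
def encoded(cohort_134):
    return rm.encode_features(cohort_134)


@pytest.fixture(scope="module")
def split(encoded):
    return rm.stratified_split(encoded, 0.3, seed=0)


class TestEncoding:
    def test_one_hot_indicators_sum_to_one(self, encoded):
        names = encoded.names
        left = encoded.X[:, names.index("artery=left")]
        right = encoded.X[:, names.index("artery=right")]
        assert np.all(left + right == 1.0)

    def test_row_count_preserved(self, cohort_134, encoded):
        assert len(encoded.X) == len(cohort_134.frame) == 134

    def test_all_numeric_frame_passes_through(self):
        df = pd.DataFrame({"pss": [1.0, 2.0], "bmi": [22.0, 30.0]})
        fm = rm.encode_features(df)
        assert fm.names == ["pss", "bmi"]
        assert np.array_equal(fm.X, df.to_numpy(float))

    def test_unknown_categorical_column_rejected(self):
        df = pd.DataFrame({"mystery": ["a", "b"]})
        with pytest.raises(ValueError, match="unknown"):
            rm.encode_features(df)

    def test_group_metadata_populated(self, encoded):
        groups = {c.name: c.group for c in encoded.columns}
        assert groups["pss"] == "simulation"
        assert groups["psv"] == "imaging"
        assert groups["smoking"] == "ecrf"


class TestSplit:
    def test_study_partition_counts(self, split):
        train, test = split
        assert np.bincount(train.y).tolist() == [80, 13]
        assert np.bincount(test.y).tolist() == [35, 6]

    def test_even_split_symmetric_case(self):
        X = np.arange(40, dtype=float).reshape(20, 2)
        y = np.repeat([0, 1], 10)
        fm = rm.FeatureMatrix(X, [rm.ColumnMeta("a", "other", False),
                                  rm.ColumnMeta("b", "other", False)], y)
        tr, te = rm.stratified_split(fm, 0.5, seed=1)
        assert np.bincount(tr.y).tolist() == [5, 5]
        assert np.bincount(te.y).tolist() == [5, 5]

    def test_seed_determinism(self, encoded):
        a = rm.stratified_split(encoded, 0.3, seed=5)[0]
        b = rm.stratified_split(encoded, 0.3, seed=5)[0]
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)

    def test_tiny_class_rejected(self):
        X = np.zeros((3, 1))
        fm = rm.FeatureMatrix(X, [rm.ColumnMeta("a", "other", False)],
                              np.array([0, 0, 1]))
        with pytest.raises(ValueError, match="fewer than 2"):
            rm.stratified_split(fm)


class TestSmote:
    def test_balances_study_split(self, split):
        out = rm.smote_oversample(split[0], seed=0)
        assert np.bincount(out.y).tolist() == [80, 80]

    def test_majority_rows_bit_identical(self, split):
        train = split[0]
        out = rm.smote_oversample(train, seed=3)
        assert out.X[: len(train.X)].tobytes() == train.X.tobytes()

    def test_synthetic_points_on_minority_segments(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0],
                      *np.random.default_rng(0).normal(5, 0.1, (9, 2))])
        y = np.array([1, 1, 1] + [0] * 9)
        cols = [rm.ColumnMeta("a", "other", False), rm.ColumnMeta("b", "other", False)]
        out = rm.smote_oversample(rm.FeatureMatrix(X, cols, y), k_neighbors=2, seed=0)
        synth = out.X[len(X):]
        lo = X[:3].min(axis=0) - 1e-12
        hi = X[:3].max(axis=0) + 1e-12
        assert np.all(synth >= lo) and np.all(synth <= hi)

    def test_binary_columns_rounded_and_clipped(self):
        X = np.column_stack([np.r_[np.zeros(3), np.ones(9)],
                             np.r_[[0.0, 1.0, 0.0], np.zeros(9)]])
        y = np.array([1] * 3 + [0] * 9)
        cols = [rm.ColumnMeta("flag", "ecrf", True), rm.ColumnMeta("x", "other", False)]
        out = rm.smote_oversample(rm.FeatureMatrix(X, cols, y), k_neighbors=2, seed=1)
        assert np.isin(out.X[:, 0], [0.0, 1.0]).all()

    def test_small_minority_shrinks_k_with_warning(self):
        X = np.vstack([np.zeros((3, 1)), np.ones((10, 1))])
        y = np.array([1] * 3 + [0] * 10)
        fm = rm.FeatureMatrix(X, [rm.ColumnMeta("a", "other", False)], y)
        with pytest.warns(UserWarning, match="reducing k"):
            out = rm.smote_oversample(fm, k_neighbors=5, seed=0)
        assert np.bincount(out.y).tolist() == [10, 10]


class TestUndersample:
    def test_matches_minority_count(self, split):
        out = rm.random_undersample(split[0], seed=0)
        assert np.bincount(out.y).tolist() == [13, 13]
        assert len(out.X) == 26

    def test_balanced_input_unchanged(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        y = np.array([0, 1, 0, 1, 0, 1])
        cols = [rm.ColumnMeta("a", "other", False), rm.ColumnMeta("b", "other", False)]
        out = rm.random_undersample(rm.FeatureMatrix(X, cols, y), seed=0)
        assert np.array_equal(np.sort(out.X, axis=0), np.sort(X, axis=0))

    def test_different_seeds_pick_different_subsets(self, split):
        a = rm.random_undersample(split[0], seed=0)
        b = rm.random_undersample(split[0], seed=1)
        assert a.X.tobytes() != b.X.tobytes()


class TestGBT:
    def test_balanced_prevalence_gives_zero_base_score(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3))
        y = np.repeat([0, 1], 20)
        cols = [rm.ColumnMeta(f"f{i}", "other", False) for i in range(3)]
        model = rm.gbt_fit(rm.FeatureMatrix(X, cols, y), n_estimators=1)
        assert model.base_score == pytest.approx(0.0, abs=1e-12)

    def test_zero_trees_predicts_base_probability(self, split):
        model = rm.gbt_fit(split[0], n_estimators=0)
        proba, _ = rm.gbt_predict(model, split[0])
        prev = split[0].y.mean()
        assert np.allclose(proba, prev)

    def test_probabilities_strictly_inside_unit_interval(self, split):
        model = rm.gbt_fit(rm.smote_oversample(split[0], seed=0), n_estimators=50)
        proba, _ = rm.gbt_predict(model, split[1])
        assert np.all((proba > 0) & (proba < 1))

    @pytest.mark.parametrize("seed", range(20))
    def test_training_log_loss_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((60, 4))
        y = (X[:, 0] + 0.5 * rng.standard_normal(60) > 0).astype(int)
        cols = [rm.ColumnMeta(f"f{i}", "other", False) for i in range(4)]
        model = rm.gbt_fit(rm.FeatureMatrix(X, cols, y), n_estimators=40)
        losses = np.array(model.train_log_loss)
        assert np.all(np.diff(losses) <= 1e-10)

    def test_separable_data_fit_accuracy(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 2))
        y = (X[:, 0] > 0).astype(int)
        cols = [rm.ColumnMeta("a", "other", False), rm.ColumnMeta("b", "other", False)]
        fm = rm.FeatureMatrix(X, cols, y)
        model = rm.gbt_fit(fm, n_estimators=100)
        _, pred = rm.gbt_predict(model, fm)
        assert (pred == y).mean() >= 0.95

    def test_single_class_train_rejected(self):
        X = np.zeros((5, 1))
        fm = rm.FeatureMatrix(X, [rm.ColumnMeta("a", "other", False)], np.zeros(5, int))
        with pytest.raises(ValueError, match="both classes"):
            rm.gbt_fit(fm)

    def test_column_mismatch_rejected(self, split):
        model = rm.gbt_fit(split[0], n_estimators=2)
        bad = rm.FeatureMatrix(split[1].X[:, :3], split[1].columns[:3], split[1].y)
        with pytest.raises(ValueError, match="match"):
            rm.gbt_predict(model, bad)

    def test_json_roundtrip_preserves_predictions(self, split, tmp_path):
        model = rm.gbt_fit(split[0], n_estimators=10)
        model.to_json(tmp_path / "model.json")
        back = rm.GBTModel.from_json(tmp_path / "model.json")
        p1, _ = rm.gbt_predict(model, split[1])
        p2, _ = rm.gbt_predict(back, split[1])
        assert np.allclose(p1, p2)


class TestEvaluation:
    def test_published_confusion_matrix_arithmetic(self):
        rep = rm.report_from_confusion(tn=32, fp=3, fn=2, tp=4)
        assert rep.accuracy == pytest.approx(36 / 41)
        assert round(100 * rep.accuracy) == 88
        assert rep.specificity == pytest.approx(32 / 35)
        assert round(rep.specificity, 2) == 0.91
        assert rep.weighted_recall == pytest.approx(rep.accuracy)

    def test_perfect_classifier_all_ones(self, split):
        train, test = split
        # a model that memorises a separable relabeling of the test set
        y = test.y
        rep = rm.report_from_confusion(
            tn=int((y == 0).sum()), fp=0, fn=0, tp=int((y == 1).sum()), auc=1.0
        )
        assert rep.sensitivity == rep.specificity == rep.balanced_accuracy == 1.0
        assert rep.f1 == 1.0 and rep.auc == 1.0

    def test_balanced_accuracy_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            tn, fp, fn, tp = rng.integers(1, 40, 4)
            rep = rm.report_from_confusion(int(tn), int(fp), int(fn), int(tp))
            assert rep.balanced_accuracy == pytest.approx(
                0.5 * (rep.sensitivity + rep.specificity), abs=1e-12
            )

    def test_zero_denominator_rates_are_undefined(self):
        rep = rm.report_from_confusion(tn=10, fp=0, fn=0, tp=0)
        assert rep.sensitivity is None
        assert rep.ppv is None
        assert rep.specificity == 1.0

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = rng.random(200)
        a1 = rm.roc_auc(y, s)
        a2 = rm.roc_auc(y, np.exp(5 * s) - 3)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_auc_matches_reference_implementation(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 300)
        y[:2] = [0, 1]
        s = rng.random(300)
        assert rm.roc_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_auc_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            rm.roc_auc(np.zeros(5, int), np.random.default_rng(0).random(5))


class TestCrossValidation:
    def test_mean_row_is_arithmetic_mean(self, split):
        reports, mean_row = rm.cross_validate(split[0], 5, "undersample", seed=0,
                                              n_estimators=20)
        for metric, value in mean_row.items():
            vals = [getattr(r, metric) for r in reports]
            if value is not None:
                assert value == pytest.approx(np.mean(vals), abs=1e-12)

    def test_stratified_fold_sizes(self, split):
        folds = rm.stratified_folds(split[0].y, 5, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1
        assert sum(sizes) == len(split[0].y)

    def test_balanced_160_rows_give_folds_of_32(self):
        y = np.repeat([0, 1], 80)
        folds = rm.stratified_folds(y, 5, seed=0)
        assert all(len(f) == 32 for f in folds)

    def test_validation_folds_keep_original_class_ratio(self, split):
        """Imbalance correction must happen inside training folds only: the
        validation folds keep the 80:13 ratio."""
        reports, _ = rm.cross_validate(split[0], 5, "smote", seed=0, n_estimators=10)
        for rep in reports:
            n1 = rep.tp + rep.fn
            n0 = rep.tn + rep.fp
            assert n1 in (2, 3) and n0 == 16
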