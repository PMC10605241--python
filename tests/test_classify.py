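import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histotex import (
    ALGORITHMS,
    FEATURE_NAMES,
    ModelSpec,
    TextureClassifier,
    classify_score,
    cross_validate_10fold,
    split_dataset,
    train,
)


def toy_table(n_per_class, rng, gap=6.0):
    """Linearly separable 33-feature table; the first two features carry signal."""
    rows = []
    for label, center in (("GBM", gap / 2), ("NORMAL", -gap / 2)):
        X = rng.normal(0, 1, size=(n_per_class, len(FEATURE_NAMES)))
        X[:, 0] += center
        X[:, 1] -= center
        for row in X:
            rows.append(dict(zip(FEATURE_NAMES, row), label=label))
    return pd.DataFrame(rows)


class TestSplitDataset:
    def test_paper_cohort_sizes(self):
        labels = np.array(["GBM"] * 1500 + ["NORMAL"] * 1500)
        plan = split_dataset(labels, seed=0)
        for part, expected in ((plan.train, 1050), (plan.validation, 225), (plan.test, 225)):
            counts = pd.Series(labels[part]).value_counts()
            assert counts["GBM"] == expected
            assert counts["NORMAL"] == expected

    def test_twenty_rows_floor_rounding(self):
        plan = split_dataset(np.array(["GBM"] * 20 + ["NORMAL"] * 20), seed=1)
        assert len(plan.train) == 28 and len(plan.validation) == 6 and len(plan.test) == 6

    def test_deterministic_per_seed(self):
        labels = np.array(["GBM"] * 50 + ["NORMAL"] * 50)
        a = split_dataset(labels, seed=5)
        b = split_dataset(labels, seed=5)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)

    def test_too_small_class_errors(self):
        with pytest.raises(ValueError):
            split_dataset(np.array(["GBM", "GBM", "NORMAL"] * 1), seed=0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(3, 200), st.integers(3, 200), st.integers(0, 2**31 - 1))
    def test_split_partitions_indices(self, n_gbm, n_normal, seed):
        labels = np.array(["GBM"] * n_gbm + ["NORMAL"] * n_normal)
        plan = split_dataset(labels, seed=seed)
        merged = np.concatenate([plan.train, plan.validation, plan.test])
        assert len(merged) == len(labels)
        assert len(np.unique(merged)) == len(labels)

    def test_group_split_keeps_patients_together(self, rng):
        labels = np.repeat(["GBM", "NORMAL"], 50)
        groups = np.array([f"p{i // 5}" for i in range(100)])
        plan = split_dataset(labels, seed=2, groups=groups)
        sets = [set(groups[plan.train]), set(groups[plan.validation]), set(groups[plan.test])]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])


class TestTextureClassifier:
    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_separable_toy_set_is_learned_perfectly(self, algo, rng):
        table = toy_table(30, rng)
        test = toy_table(15, np.random.default_rng(77))
        model = train(algo, table, seed=0)
        assert (model.predict(table) == table["label"]).all()  # zero training errors
        assert (model.predict(test) == test["label"]).mean() == 1.0

    @pytest.mark.parametrize("algo", ["dt", "svm", "lm"])
    def test_shuffled_labels_give_chance_accuracy(self, algo):
        rng = np.random.default_rng(13)
        table = toy_table(100, rng, gap=0.0)
        test = toy_table(100, np.random.default_rng(14), gap=0.0)
        model = train(algo, table, seed=0)
        acc = (model.predict(test) == test["label"]).mean()
        assert 0.35 < acc < 0.65

    def test_same_seed_identical_predictions(self, rng):
        table = toy_table(25, rng, gap=1.0)
        a = train("rf", table, seed=9).predict_score(table)
        b = train("rf", table, seed=9).predict_score(table)
        np.testing.assert_array_equal(a, b)

    def test_scores_bounded_in_unit_interval(self, rng):
        table = toy_table(20, rng)
        queries = pd.DataFrame(
            rng.normal(0, 50, size=(1000, len(FEATURE_NAMES))), columns=FEATURE_NAMES
        )
        for algo in ALGORITHMS:
            s = train(algo, table, seed=0).predict_score(queries)
            assert (s >= 0.0).all() and (s <= 1.0).all()

    def test_equidistant_query_scores_near_half(self, rng):
        table = toy_table(50, rng)
        midpoint = pd.DataFrame([dict.fromkeys(FEATURE_NAMES, 0.0)])
        score = train("lm", table, seed=0).predict_score(midpoint)[0]
        assert score == pytest.approx(0.5, abs=0.1)

    def test_single_class_training_errors(self, rng):
        table = toy_table(10, rng)
        table["label"] = "GBM"
        with pytest.raises(ValueError):
            train("svm", table, seed=0)

    def test_nan_features_rejected(self, rng):
        table = toy_table(10, rng)
        model = train("dt", table, seed=0)
        bad = table[FEATURE_NAMES].copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            model.predict_score(bad)

    def test_lm_score_monotone_in_positive_weight_feature(self, rng):
        table = toy_table(50, rng)
        model = train("lm", table, seed=0)
        # feature 0 is shifted up for GBM, so its logistic weight is positive
        base = pd.DataFrame([dict.fromkeys(FEATURE_NAMES, 0.0)])
        scores = []
        for v in np.linspace(-3, 3, 7):
            q = base.copy()
            q[FEATURE_NAMES[0]] = v
            scores.append(model.predict_score(q)[0])
        assert (np.diff(scores) >= 0).all()

    def test_validation_tuning_selects_from_grid(self, rng):
        table = toy_table(30, rng)
        val = toy_table(10, np.random.default_rng(5))
        model = train("svm", table, val, seed=0, tune=True)
        assert (model.predict(val) == val["label"]).mean() == 1.0


class TestClassifyScore:
    @pytest.mark.parametrize("score,expected", [(0.49, "NORMAL"), (0.5, "GBM"), (1.0, "GBM"), (0.0, "NORMAL")])
    def test_half_threshold_with_tie_to_gbm(self, score, expected):
        assert classify_score(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_score(1.2)


class TestCrossValidate:
    def test_hundred_rows_give_folds_of_ten(self, rng):
        table = toy_table(50, rng)  # 100 rows total
        result = cross_validate_10fold("dt", table, seed=0)
        folds = result[result["fold"] != "mean"]
        assert (folds["n_test"] == 10).all()
        assert folds["n_test"].sum() == 100

    def test_deterministic_per_seed(self, rng):
        table = toy_table(20, rng, gap=1.5)
        a = cross_validate_10fold("svm", table, seed=3)
        b = cross_validate_10fold("svm", table, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_separable_cohort_reaches_perfect_mean_accuracy(self, rng):
        table = toy_table(40, rng, gap=10.0)
        result = cross_validate_10fold("svm", table, seed=0)
        assert result[result["fold"] == "mean"]["accuracy"].iloc[0] == 1.0

    def test_too_few_rows_error(self, rng):
        table = toy_table(5, rng)
        with pytest.raises(ValueError):
            cross_validate_10fold("dt", table, seed=0)

    def test_invalid_algorithm_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("mlp")
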