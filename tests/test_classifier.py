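import numpy as np
import pytest

from mbmetagene import (
    SUBGROUP_LABELS,
    evaluate,
    metrics_from_confusion,
    minmax_scale,
    misclassification_report,
    roc_curve_ovr,
    stratified_split,
    tune_and_train,
)


def auc_by_pair_counting(labels, scores, positive_class):
    """Independent oracle: exhaustive positive/negative pair comparison."""
    pos = [s for l, s in zip(labels, scores) if l == positive_class]
    neg = [s for l, s in zip(labels, scores) if l != positive_class]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def separable_clusters(rng, n_per_class=12, spread=0.02):
    """Seven tight, well-separated clusters in 6-d metagene space."""
    anchors = np.vstack([np.eye(6), 0.5 * (np.eye(6)[0] + np.eye(6)[3])])
    X, y = [], []
    for c, label in enumerate(SUBGROUP_LABELS):
        pts = anchors[c] + rng.normal(0, spread, size=(n_per_class, 6))
        X.append(np.clip(pts, 0, None))
        y.extend([label] * n_per_class)
    return np.vstack(X), y


class TestStratifiedSplit:
    def test_ceil_rule_per_class(self):
        labels = (
            ["WNT"] * 33 + ["SHH-Child"] * 38 + ["SHH-Infant"] * 65
            + ["Group3-HighRisk"] * 65 + ["Group3-LowRisk"] * 50
            + ["Group4-HighRisk"] * 85 + ["Group4-LowRisk"] * 73
        )
        split = stratified_split(labels, 0.8, seed=0)
        assert split.train_counts == {
            "WNT": 27, "SHH-Child": 31, "SHH-Infant": 52,
            "Group3-HighRisk": 52, "Group3-LowRisk": 40,
            "Group4-HighRisk": 68, "Group4-LowRisk": 59,
        }
        assert split.n_train == 329 and split.n_test == 80
        pct = split.train_percentages()
        assert pct["SHH-Infant"] == 15.81
        assert pct["Group4-HighRisk"] == 20.67

    def test_disjoint_and_exhaustive(self):
        labels = ["WNT"] * 10 + ["SHH-Child"] * 15
        split = stratified_split(labels, 0.8, seed=3)
        joint = set(split.train_indices) | set(split.test_indices)
        assert joint == set(range(25))
        assert not set(split.train_indices) & set(split.test_indices)

    def test_fraction_one_gives_empty_test_with_warning(self):
        labels = ["WNT"] * 5 + ["SHH-Child"] * 5
        with pytest.warns(UserWarning, match="empty test"):
            split = stratified_split(labels, 1.0, seed=0)
        assert split.n_test == 0 and split.n_train == 10

    def test_same_seed_identical(self):
        labels = ["WNT"] * 20 + ["SHH-Child"] * 30
        a = stratified_split(labels, 0.8, seed=9)
        b = stratified_split(labels, 0.8, seed=9)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(["WNT", "SHH-Child", "SHH-Child"], 0.8, seed=0)


class TestMinMaxScale:
    def test_affine_mapping(self):
        train = np.array([[2.0], [4.0], [3.0]])
        scaled, scaler = minmax_scale(train)
        assert scaled[2, 0] == pytest.approx(0.5)

    def test_out_of_range_other_set_clipped(self):
        train = np.array([[2.0], [4.0]])
        _, other, _ = minmax_scale(train, np.array([[5.0], [1.0]]))
        assert other[0, 0] == 1.0 and other[1, 0] == 0.0

    def test_constant_feature_maps_to_zero(self):
        train = np.full((4, 2), 3.0)
        train[:, 1] = [0, 1, 2, 3]
        scaled, other, _ = minmax_scale(train, np.array([[7.0, 2.0]]))
        assert (scaled[:, 0] == 0).all()
        assert other[0, 0] == 0.0


class TestTuneAndTrain:
    @pytest.mark.parametrize("family", ["svm_rbf", "random_forest", "gradient_boosting", "knn"])
    def test_separable_clusters_training_accuracy_one(self, family):
        rng = np.random.default_rng(1)
        X, y = separable_clusters(rng)
        model = tune_and_train(X, y, family=family, n_candidates=3, cv_folds=5, seed=0)
        assert model.predict(X) == y

    def test_probabilities_normalized(self):
        rng = np.random.default_rng(2)
        X, y = separable_clusters(rng)
        model = tune_and_train(X, y, family="knn", n_candidates=2, cv_folds=5, seed=0)
        P = model.predict_proba(X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert (P >= 0).all()

    def test_same_seed_same_selected_configuration(self):
        rng = np.random.default_rng(3)
        X, y = separable_clusters(rng, n_per_class=8)
        a = tune_and_train(X, y, family="svm_rbf", n_candidates=4, cv_folds=4, seed=5)
        b = tune_and_train(X, y, family="svm_rbf", n_candidates=4, cv_folds=4, seed=5)
        assert a.config == b.config

    def test_too_few_samples_for_folds(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            tune_and_train(X, ["WNT", "WNT", "SHH-Child", "SHH-Child"], cv_folds=10)


class TestMetricsFromConfusion:
    def test_perfect_predictions_all_ones(self):
        C = np.diag([5, 3, 7])
        m = metrics_from_confusion(C, ["a", "b", "c"])
        assert m["accuracy"] == 1.0
        assert m["macro_recall"] == 1.0
        assert m["macro_precision"] == 1.0
        assert m["macro_f1"] == 1.0
        assert m["balanced_accuracy_sens_spec"] == 1.0

    def test_constant_prediction_balanced_two_class(self):
        # predicting one class always on balanced 2-class data: chance level
        C = np.array([[10, 0], [10, 0]])
        m = metrics_from_confusion(C, ["a", "b"])
        assert m["balanced_accuracy_macro_recall"] == pytest.approx(0.5)
        assert m["balanced_accuracy_sens_spec"] == pytest.approx(0.5)

    def test_macro_recall_equals_table_formula(self):
        rng = np.random.default_rng(4)
        C = rng.integers(0, 20, size=(4, 4))
        m = metrics_from_confusion(C, list("abcd"))
        recalls = [C[i, i] / C[i].sum() for i in range(4)]
        assert m["balanced_accuracy_macro_recall"] == pytest.approx(np.mean(recalls))

    def test_sens_spec_identity(self):
        # balanced_accuracy_sens_spec == (macro recall + macro specificity)/2
        rng = np.random.default_rng(5)
        C = rng.integers(1, 15, size=(5, 5))
        m = metrics_from_confusion(C, list("abcde"))
        spec = []
        total = C.sum()
        for i in range(5):
            tp = C[i, i]
            fp = C[:, i].sum() - tp
            tn = total - C[i].sum() - fp
            spec.append(tn / (tn + fp))
        expected = (m["macro_recall"] + np.mean(spec)) / 2
        assert m["balanced_accuracy_sens_spec"] == pytest.approx(expected)

    def test_binary_conventions_coincide(self):
        # for 2 classes macro recall over {+,-} equals (sens+spec)/2
        C = np.array([[8, 2], [3, 7]])
        m = metrics_from_confusion(C, ["pos", "neg"])
        assert m["balanced_accuracy_macro_recall"] == pytest.approx(
            m["balanced_accuracy_sens_spec"]
        )

    def test_absent_class_excluded_with_warning(self):
        C = np.array([[5, 0, 0], [1, 4, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="no true members"):
            m = metrics_from_confusion(C, ["a", "b", "c"])
        assert np.isnan(m["per_class"].set_index("class").loc["c", "recall"])
        assert m["macro_recall"] == pytest.approx((1.0 + 0.8) / 2)


class TestEvaluate:
    def test_perfect_model_every_metric_one(self):
        rng = np.random.default_rng(6)
        X, y = separable_clusters(rng)
        model = tune_and_train(X, y, family="knn", n_candidates=2, cv_folds=5, seed=0)
        report = evaluate(model, X, y)
        assert report.accuracy == 1.0
        assert report.balanced_accuracy_sens_spec == 1.0
        assert report.macro_auc == pytest.approx(1.0)
        assert np.trace(report.confusion) == len(y)

    def test_label_permuted_perfect_predictor_permutes_confusion(self):
        rng = np.random.default_rng(7)
        X, y = separable_clusters(rng)
        model = tune_and_train(X, y, family="knn", n_candidates=2, cv_folds=5, seed=0)
        # permute true labels: confusion rows move to the permuted classes
        perm = {a: b for a, b in zip(SUBGROUP_LABELS, SUBGROUP_LABELS[1:] + SUBGROUP_LABELS[:1])}
        y_perm = [perm[l] for l in y]
        report = evaluate(model, X, y_perm)
        idx = {c: i for i, c in enumerate(report.class_names)}
        for orig, moved in perm.items():
            assert report.confusion[idx[moved], idx[orig]] == 12

    def test_confusion_row_sums_match_class_counts(self):
        rng = np.random.default_rng(8)
        X, y = separable_clusters(rng, spread=0.4)  # noisy: some errors
        model = tune_and_train(X, y, family="knn", n_candidates=2, cv_folds=5, seed=0)
        report = evaluate(model, X, y)
        idx = {c: i for i, c in enumerate(report.class_names)}
        for c in set(y):
            assert report.confusion[idx[c]].sum() == y.count(c)


class TestMisclassificationReport:
    def test_row_contents_for_misclassified_sample(self):
        classes = ["A", "B", "C"]
        P = np.array([[0.30, 0.33, 0.37]])  # argmax is C
        table = misclassification_report(["A"], ["C"], P, classes)
        row = table.iloc[0]
        assert row["true_label"] == "A" and row["predicted_label"] == "C"
        assert row["true_label_probability"] == pytest.approx(0.30)
        assert row["predicted_label_probability"] == pytest.approx(0.37)
        assert row["predicted_label_probability"] >= row["true_label_probability"]

    def test_no_misclassifications_empty_table(self):
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        table = misclassification_report(["A", "B"], ["A", "B"], P, ["A", "B"])
        assert len(table) == 0

    def test_probabilities_not_summing_to_one_rejected(self):
        P = np.array([[0.5, 0.4]])
        with pytest.raises(ValueError, match="sums"):
            misclassification_report(["A"], ["A"], P, ["A", "B"])

    def test_argmax_inconsistency_rejected(self):
        P = np.array([[0.7, 0.3]])
        with pytest.raises(ValueError, match="argmax"):
            misclassification_report(["A"], ["B"], P, ["A", "B"])


class TestRocCurveOvr:
    def test_perfectly_ordered_scores_auc_one(self):
        labels = ["+", "+", "-", "-"]
        _, auc = roc_curve_ovr(labels, [0.9, 0.8, 0.2, 0.1], "+")
        assert auc == 1.0

    def test_all_identical_scores_auc_half(self):
        labels = ["+", "-", "+", "-"]
        _, auc = roc_curve_ovr(labels, [0.5] * 4, "+")
        assert auc == 0.5

    def test_derived_example_five_sixths(self):
        labels = ["+", "+", "-", "+", "-"]
        scores = [0.9, 0.8, 0.4, 0.35, 0.1]
        _, auc = roc_curve_ovr(labels, scores, "+")
        assert auc == pytest.approx(5 / 6)
        assert auc == pytest.approx(auc_by_pair_counting(labels, scores, "+"))

    def test_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(4, 30))
            labels = ["+" if rng.random() < 0.4 else "-" for _ in range(n)]
            if "+" not in labels or "-" not in labels:
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            _, auc = roc_curve_ovr(labels, scores, "+")
            assert auc == pytest.approx(auc_by_pair_counting(labels, scores, "+"))

    def test_equals_trapezoidal_area(self):
        rng = np.random.default_rng(10)
        labels = ["+" if rng.random() < 0.5 else "-" for _ in range(40)]
        scores = rng.choice(np.round(rng.uniform(0, 1, 8), 3), size=40)
        if "+" not in labels or "-" not in labels:
            pytest.skip("degenerate draw")
        points, auc = roc_curve_ovr(labels, scores, "+")
        pts = np.array(points)
        assert auc == pytest.approx(np.trapezoid(pts[:, 1], pts[:, 0]))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        labels = ["+" if rng.random() < 0.5 else "-" for _ in range(30)]
        scores = rng.uniform(0, 1, 30)
        _, a = roc_curve_ovr(labels, scores, "+")
        _, b = roc_curve_ovr(labels, np.exp(5 * scores), "+")
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_ovr(["+", "+"], [0.1, 0.2], "+")
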