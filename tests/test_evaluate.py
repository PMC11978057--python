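import numpy as np
import pandas as pd
import pytest

from macaqueid import classify, evaluate


class LabelCodeExtractor:
    """Test double: the feature IS the label code (perfectly informative)."""

    scheme = "label-code"

    def __init__(self, codes):
        self._codes = np.asarray(codes, dtype=float)
        self.fit_history = []

    def prepare(self, images):
        pass

    def fit(self, train_indices):
        self.fit_history.append(np.asarray(train_indices).copy())

    def transform(self, indices):
        return self._codes[np.asarray(indices)].reshape(-1, 1)


class _ConstantModel:
    def __init__(self, classes, target):
        self.classes = np.asarray(classes)
        self._target = target

    def predict(self, X):
        return np.repeat(self._target, len(np.atleast_2d(X)))

    def predict_confidence(self, X):
        out = np.zeros((len(np.atleast_2d(X)), len(self.classes)))
        out[:, list(self.classes).index(self._target)] = 1.0
        return out


def constant_trainer(X, y, seed):
    classes = np.unique(y)
    return _ConstantModel(classes, classes[0])


def knn1_trainer(X, y, seed):
    return classify.train(X, list(y), classify.ClassifierSpec("KNN", fixed_params={"k": 1}), seed)


@pytest.fixture
def balanced_4class():
    y = [c for c in "abcd" for _ in range(12)]
    codes = [ord(c) for c in y]
    images = [np.zeros((4, 4))] * len(y)  # unused by the label-code extractor
    return images, y, codes


class TestPerClassPrecision:
    def test_diagonal_confusion_gives_ones(self):
        conf = pd.DataFrame(np.diag([5, 3, 2]), index=list("abc"), columns=list("abc"))
        assert evaluate.per_class_precision(conf) == {"a": 1.0, "b": 1.0, "c": 1.0}

    def test_hand_arithmetic_two_class(self):
        conf = pd.DataFrame([[8, 2], [4, 6]], index=list("AB"), columns=list("AB"))
        prec = evaluate.per_class_precision(conf)
        assert prec["A"] == pytest.approx(8 / 12)
        assert prec["B"] == pytest.approx(6 / 8)

    def test_never_predicted_class_absent(self):
        conf = pd.DataFrame([[5, 0], [3, 0]], index=list("AB"), columns=list("AB"))
        assert "B" not in evaluate.per_class_precision(conf)


class TestCrossValidate:
    def test_perfectly_informative_features_score_one(self, balanced_4class):
        images, y, codes = balanced_4class
        rep = evaluate.cross_validate(images, y, LabelCodeExtractor(codes),
                                      trainer=knn1_trainer, folds=10, seed=0)
        assert np.all(rep.fold_accuracies == 1.0)
        assert rep.mean_accuracy == 1.0

    def test_constant_classifier_on_balanced_four_classes(self, balanced_4class):
        images, y, codes = balanced_4class
        rep = evaluate.cross_validate(images, y, LabelCodeExtractor(codes),
                                      trainer=constant_trainer, folds=12, seed=0)
        assert rep.pooled_accuracy == pytest.approx(0.25)
        assert rep.mean_accuracy == pytest.approx(0.25)

    def test_stratification_error_names_class(self, balanced_4class):
        images, y, codes = balanced_4class
        y = list(y); y[0] = "rare"  # a 1-sample class
        with pytest.raises(evaluate.StratificationError, match="rare"):
            evaluate.cross_validate(images, y, LabelCodeExtractor(codes),
                                    trainer=knn1_trainer, folds=10, seed=0)

    def test_fold_disjointness_and_coverage(self, balanced_4class):
        images, y, codes = balanced_4class
        rep = evaluate.cross_validate(images, y, LabelCodeExtractor(codes),
                                      trainer=knn1_trainer, folds=10, seed=3)
        assign = rep.fold_assignment
        assert len(assign) == len(y)
        assert set(assign) == set(range(10))
        # each sample tested exactly once: confusion row sums = class counts
        counts = pd.Series(y).value_counts()
        for cls in counts.index:
            assert rep.confusion.loc[cls].sum() == counts[cls]

    def test_fit_history_never_contains_test_indices(self, balanced_4class):
        images, y, codes = balanced_4class
        rep = evaluate.cross_validate(images, y, LabelCodeExtractor(codes),
                                      trainer=knn1_trainer, folds=10, seed=1)
        assert len(rep.fit_history) == 10
        for f, fitted in enumerate(rep.fit_history):
            test_idx = np.flatnonzero(rep.fold_assignment == f)
            assert len(np.intersect1d(fitted, test_idx)) == 0
            assert len(fitted) + len(test_idx) == len(y)

    def test_mean_accuracy_invariant_to_relabeling(self, balanced_4class):
        images, y, codes = balanced_4class
        rep1 = evaluate.cross_validate(images, y, LabelCodeExtractor(codes),
                                       trainer=knn1_trainer, folds=10, seed=5)
        renamed = [{"a": "z9", "b": "q1", "c": "m3", "d": "k7"}[c] for c in y]
        rep2 = evaluate.cross_validate(images, renamed, LabelCodeExtractor(codes),
                                       trainer=knn1_trainer, folds=10, seed=5)
        assert rep1.mean_accuracy == rep2.mean_accuracy


class TestComparisonGrid:
    def test_single_cell_matches_direct_cross_validate(self, balanced_4class):
        images, y, codes = balanced_4class
        spec = classify.ClassifierSpec("KNN", fixed_params={"k": 1})
        ext = LabelCodeExtractor(codes)
        grid, reports = evaluate.comparison_grid(images, y, extractors=[ext],
                                                 classifiers=[spec], folds=10, seed=4)
        assert grid.shape == (1, 1)
        direct = evaluate.cross_validate(images, y, LabelCodeExtractor(codes),
                                         spec, folds=10, seed=4)
        cell = reports[("KNN", "label-code")]
        assert np.array_equal(cell.fold_accuracies, direct.fold_accuracies)
        assert grid.iloc[0, 0] == round(100 * direct.pooled_accuracy, 2)

    def test_failed_cell_marked_and_grid_completes(self, balanced_4class):
        images, y, codes = balanced_4class

        class ExplodingSpec:
            name = "broken"
        # a spec object classify.train cannot handle -> cell fails, grid survives
        good = classify.ClassifierSpec("KNN", fixed_params={"k": 1})
        grid, reports = evaluate.comparison_grid(
            images, y, extractors=[LabelCodeExtractor(codes)],
            classifiers=[ExplodingSpec(), good], folds=10, seed=0)
        assert np.isnan(grid.loc["broken"].iloc[0])
        assert not np.isnan(grid.loc["KNN"].iloc[0])
        assert ("KNN", "label-code") in reports
        assert ("broken", "label-code") not in reports

    def test_same_fold_assignment_reused_across_cells(self, balanced_4class):
        images, y, codes = balanced_4class
        spec = classify.ClassifierSpec("KNN", fixed_params={"k": 1})
        e1, e2 = LabelCodeExtractor(codes), LabelCodeExtractor(codes)
        e2.scheme = "label-code-2"
        grid, reports = evaluate.comparison_grid(
            images, y, extractors=[e1, e2], classifiers=[spec], folds=10, seed=2)
        (r1, r2) = reports.values()
        assert np.array_equal(r1.fold_assignment, r2.fold_assignment)
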