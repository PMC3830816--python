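import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctgsvm import (
    ConfusionMatrix,
    ConfusionRatioMatrix,
    SwarmConfig,
    SyntheticSpec,
    chance_ratio_matrix,
    cobweb_coordinates,
    column_normalize,
    cross_validate,
    ctg_plan,
    generate_synthetic,
    one_vs_rest,
    overall_accuracy,
    render_cobweb,
    sensitivity_specificity,
    stratified_kfold,
)
from ctgsvm import evaluation
from ctgsvm.exceptions import (
    DomainError,
    NormalizationError,
    StratificationError,
    UndefinedRateError,
)

CLASSES = ("normal", "suspect", "pathologic")

# 3x3 counts: rows predicted, columns actual (published-style layout)
REFERENCE_COUNTS = np.array([
    [1604, 70, 12],
    [38, 208, 29],
    [13, 17, 135],
])


@pytest.fixture
def reference_cm():
    return ConfusionMatrix(counts=REFERENCE_COUNTS, class_order=CLASSES)


# ------------------------------------------------------------ stratified CV

class TestStratifiedKfold:
    def test_exact_divisibility(self):
        labels = np.repeat(["a", "b", "c"], 10)
        folds = stratified_kfold(labels, k=10, seed=0)
        for f in range(1, 11):
            test = folds.test_indices(f)
            assert len(test) == 3
            assert sorted(labels[test]) == ["a", "b", "c"]

    def test_imbalanced_fold_counts(self):
        labels = np.repeat(["n", "s", "p"], [1655, 295, 176])
        folds = stratified_kfold(labels, k=10, seed=1)
        expected = {"n": {165, 166}, "s": {29, 30}, "p": {17, 18}}
        for cls, allowed in expected.items():
            per_fold = [np.sum(labels[folds.test_indices(f)] == cls)
                        for f in range(1, 11)]
            assert set(per_fold) <= allowed

    def test_same_seed_identical(self):
        labels = np.repeat(["a", "b"], [40, 25])
        a = stratified_kfold(labels, 5, seed=7)
        b = stratified_kfold(labels, 5, seed=7)
        assert np.array_equal(a.fold_index, b.fold_index)

    def test_small_class_error_names_class(self):
        labels = np.array(["a"] * 20 + ["rare"] * 3)
        with pytest.raises(StratificationError, match="rare"):
            stratified_kfold(labels, 5, seed=0)

    @settings(max_examples=25, deadline=None)
    @given(
        n_a=st.integers(6, 60),
        n_b=st.integers(6, 60),
        k=st.integers(2, 6),
        seed=st.integers(0, 1000),
    )
    def test_partition_and_balance(self, n_a, n_b, k, seed):
        labels = np.repeat(["a", "b"], [n_a, n_b])
        folds = stratified_kfold(labels, k, seed)
        assert set(np.unique(folds.fold_index)) == set(range(1, k + 1))
        # disjoint cover
        assert sum(len(folds.test_indices(f)) for f in range(1, k + 1)) == \
            n_a + n_b
        # per-class balance within 1
        for cls in ("a", "b"):
            per_fold = [int(np.sum(labels[folds.test_indices(f)] == cls))
                        for f in range(1, k + 1)]
            assert max(per_fold) - min(per_fold) <= 1


# ---------------------------------------------------------------- matrices

class TestConfusionMatrix:
    def test_from_labels_counts_and_orientation(self):
        actual = ["a", "a", "b", "b", "b"]
        predicted = ["a", "b", "b", "b", "a"]
        cm = ConfusionMatrix.from_labels(actual, predicted, ("a", "b"))
        # rows predicted, columns actual
        assert cm.counts[0, 0] == 1  # predicted a, actual a
        assert cm.counts[1, 0] == 1  # predicted b, actual a
        assert cm.counts[0, 1] == 1  # predicted a, actual b
        assert cm.counts[1, 1] == 2
        assert np.array_equal(cm.column_totals(), [2, 3])

    def test_reference_column_totals(self, reference_cm):
        assert np.array_equal(reference_cm.column_totals(),
                              [1655, 295, 176])
        assert reference_cm.total == 2126


class TestOverallAccuracy:
    def test_identity_counts(self):
        cm = ConfusionMatrix(counts=np.diag([5, 3, 2]), class_order=CLASSES)
        assert overall_accuracy(cm) == 1.0

    def test_uniform_counts(self):
        cm = ConfusionMatrix(counts=np.full((3, 3), 4), class_order=CLASSES)
        assert overall_accuracy(cm) == pytest.approx(1.0 / 3.0)

    def test_reference_pooled_accuracy(self, reference_cm):
        assert overall_accuracy(reference_cm) == pytest.approx(
            (1604 + 208 + 135) / 2126)

    def test_empty_matrix(self):
        cm = ConfusionMatrix(counts=np.zeros((2, 2), dtype=int),
                             class_order=("a", "b"))
        with pytest.raises(DomainError):
            overall_accuracy(cm)

    def test_permutation_invariance(self, reference_cm, rng):
        perm = rng.permutation(3)
        permuted = ConfusionMatrix(
            counts=reference_cm.counts[np.ix_(perm, perm)],
            class_order=tuple(np.array(CLASSES)[perm]))
        assert overall_accuracy(permuted) == overall_accuracy(reference_cm)


class TestColumnNormalize:
    def test_reference_ratio_matrix_3dp(self, reference_cm):
        expected = np.array([
            [0.969, 0.237, 0.068],
            [0.023, 0.705, 0.165],
            [0.008, 0.058, 0.767],
        ])
        assert np.array_equal(column_normalize(reference_cm).rounded(3),
                              expected)

    def test_columns_sum_to_one(self, reference_cm):
        ratios = column_normalize(reference_cm).ratios
        assert np.abs(ratios.sum(axis=0) - 1.0).max() < 1e-12

    def test_identity_predictions(self):
        cm = ConfusionMatrix(counts=np.diag([9, 9, 9]), class_order=CLASSES)
        assert np.array_equal(column_normalize(cm).ratios, np.eye(3))

    def test_zero_column_names_class(self):
        counts = np.diag([5, 0, 5])
        cm = ConfusionMatrix(counts=counts, class_order=CLASSES)
        with pytest.raises(NormalizationError, match="suspect"):
            column_normalize(cm)


class TestSensitivitySpecificity:
    def test_perfect(self):
        cm = ConfusionMatrix(counts=np.array([[10, 0], [0, 20]]),
                             class_order=("pos", "neg"))
        assert sensitivity_specificity(cm) == (1.0, 1.0)

    def test_hand_values(self):
        cm = ConfusionMatrix(counts=np.array([[50, 20], [50, 80]]),
                             class_order=("pos", "neg"))
        sens, spec = sensitivity_specificity(cm)
        assert sens == pytest.approx(0.5)
        assert spec == pytest.approx(0.8)

    def test_reference_normal_vs_rest(self, reference_cm):
        sens, spec = sensitivity_specificity(
            one_vs_rest(reference_cm, "normal"))
        assert sens == pytest.approx(1604 / 1655, abs=1e-12)
        # predicted-normal errors: 70 + 12; actual non-normal total: 471
        assert spec == pytest.approx((471 - 82) / 471, abs=1e-12)

    @pytest.mark.parametrize("counts,which", [
        ([[0, 5], [0, 5]], "sensitivity"),
        ([[5, 0], [5, 0]], "specificity"),
    ])
    def test_zero_denominators(self, counts, which):
        cm = ConfusionMatrix(counts=np.array(counts),
                             class_order=("pos", "neg"))
        with pytest.raises(UndefinedRateError, match=which):
            sensitivity_specificity(cm)


# ------------------------------------------------------------------ cobweb

class TestCobweb:
    def test_chance_classifier_axes(self):
        polygon = cobweb_coordinates(chance_ratio_matrix(CLASSES))
        assert len(polygon.axes) == 6
        assert np.allclose(np.round(polygon.values, 2), 0.33)
        assert polygon.chance_value == pytest.approx(1.0 / 3.0)

    def test_perfect_classifier(self):
        crm = ConfusionRatioMatrix(ratios=np.eye(3), class_order=CLASSES)
        assert np.all(cobweb_coordinates(crm).values == 0.0)

    def test_reference_off_diagonal_values(self, reference_cm):
        polygon = cobweb_coordinates(column_normalize(reference_cm))
        values = set(np.round(polygon.values, 3))
        assert values == {0.237, 0.068, 0.023, 0.165, 0.008, 0.058}

    def test_axis_count_r_squared_minus_r(self):
        for r in (2, 3, 4, 5):
            order = tuple(f"c{i}" for i in range(r))
            polygon = cobweb_coordinates(chance_ratio_matrix(order))
            assert len(polygon.axes) == r * r - r

    def test_axis_ordering_column_major(self, reference_cm):
        polygon = cobweb_coordinates(column_normalize(reference_cm))
        assert polygon.axes[0] == ("suspect", "normal")
        assert polygon.axes[1] == ("pathologic", "normal")
        assert polygon.axes[2] == ("normal", "suspect")

    def test_within_chance(self, reference_cm):
        polygon = cobweb_coordinates(column_normalize(reference_cm))
        assert polygon.within_chance()
        chance = cobweb_coordinates(chance_ratio_matrix(CLASSES))
        assert not chance.within_chance()

    @pytest.mark.parametrize("suffix", [".svg", ".png"])
    def test_render_writes_file(self, tmp_path, reference_cm, suffix):
        polygon = cobweb_coordinates(column_normalize(reference_cm))
        path = tmp_path / f"cobweb{suffix}"
        render_cobweb(polygon, path, title="reference")
        assert path.exists() and path.stat().st_size > 0


# ---------------------------------------------------------- cross-validate

class TestCrossValidate:
    @pytest.fixture
    def small_dataset(self):
        return generate_synthetic(SyntheticSpec(n_per_class=(30, 20, 15),
                                                dim=5, separation=4.0,
                                                seed=11))

    def test_perfect_stub_classifier(self, small_dataset, monkeypatch):
        lookup = {row.tobytes(): label
                  for row, label in zip(small_dataset.X, small_dataset.y)}

        class StubTree:
            node_models = ()

        monkeypatch.setattr(evaluation.tree_mod, "fit_tree",
                            lambda data, plan, cfg, **kw: StubTree())
        monkeypatch.setattr(
            evaluation.tree_mod, "predict_tree",
            lambda tree, X: np.array([lookup[row.tobytes()] for row in X],
                                     dtype=object))
        result = cross_validate(small_dataset, ctg_plan(), SwarmConfig(),
                                k=5, seed=0)
        assert result.fold_accuracies == [1.0] * 5
        assert result.mean_accuracy == 1.0
        assert np.array_equal(np.diag(result.confusion.counts),
                              [30, 20, 15])

    def test_pooled_total_equals_dataset_size(self, small_dataset,
                                              tiny_swarm):
        result = cross_validate(small_dataset, ctg_plan(), tiny_swarm,
                                k=3, seed=4, inner_cv_folds=2)
        assert result.confusion.total == len(small_dataset)
        assert len(result.fold_accuracies) == 3
        assert len(result.fold_hyperparameters) == 3
        assert all(len(h) == 2 for h in result.fold_hyperparameters)

    def test_separable_data_high_accuracy(self, small_dataset, tiny_swarm):
        result = cross_validate(small_dataset, ctg_plan(), tiny_swarm,
                                k=3, seed=4, inner_cv_folds=2)
        assert result.mean_accuracy >= 0.9

    def test_determinism(self, small_dataset, tiny_swarm):
        a = cross_validate(small_dataset, ctg_plan(), tiny_swarm,
                           k=3, seed=4, inner_cv_folds=2)
        b = cross_validate(small_dataset, ctg_plan(), tiny_swarm,
                           k=3, seed=4, inner_cv_folds=2)
        assert a.fold_accuracies == b.fold_accuracies
        assert np.array_equal(a.confusion.counts, b.confusion.counts)
        assert a.fold_hyperparameters == b.fold_hyperparameters
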