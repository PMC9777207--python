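"""Evaluation: grouped folds, case aggregation, confusion-matrix metrics,
ROC/AUC, and probability-map rendering."""

import matplotlib
import numpy as np
import pytest

from fibropath.evaluation import (
    ConfusionMatrix,
    UndefinedMetricError,
    binary_metrics,
    case_probability,
    grouped_kfold,
    probability_to_color,
    render_probability_map,
    roc_auc,
)
from fibropath.tiling import PatchRecord


def case_cohort(n_per_class):
    labels = {}
    for i in range(n_per_class):
        labels[f"ipf_{i:02d}"] = 1
        labels[f"non_{i:02d}"] = 0
    return labels


class TestGroupedKfold:
    def test_24_cases_5_folds_sizes(self):
        folds = grouped_kfold(case_cohort(12), k=5, seed=0)
        for cls in (0, 1):
            sizes = sorted(
                sum(
                    1
                    for c, f in folds.fold_of.items()
                    if f == fold and (c.startswith("ipf") == (cls == 1))
                )
                for fold in range(5)
            )
            assert sizes == [2, 2, 2, 3, 3]

    def test_leave_one_case_out(self):
        folds = grouped_kfold(case_cohort(3), k=3, seed=1)
        for fold in range(3):
            per_class = {0: 0, 1: 0}
            for c in folds.test_cases(fold):
                per_class[1 if c.startswith("ipf") else 0] += 1
            assert per_class == {0: 1, 1: 1}

    def test_partition_property(self):
        labels = case_cohort(7)
        folds = grouped_kfold(labels, k=5, seed=3)
        all_test = [c for f in range(5) for c in folds.test_cases(f)]
        assert sorted(all_test) == sorted(labels)  # disjoint cover

    def test_deterministic_under_seed(self):
        a = grouped_kfold(case_cohort(6), k=5, seed=9)
        b = grouped_kfold(case_cohort(6), k=5, seed=9)
        assert a.fold_of == b.fold_of

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            grouped_kfold(case_cohort(4), k=5)


class TestCaseProbability:
    def test_mean_examples(self):
        assert case_probability([0.2, 0.4, 0.6]) == pytest.approx(0.4)
        assert case_probability([0.73]) == pytest.approx(0.73)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            case_probability([])

    def test_uniform_draws_concentrate_at_half(self):
        draws = np.random.default_rng(0).uniform(size=1000)
        se = np.sqrt(1 / 12 / 1000)
        assert abs(case_probability(draws) - 0.5) < 3 * se


class TestBinaryMetrics:
    def test_no_augmentation_matrix_specificity(self):
        # best model without GAN augmentation: 7 TN, 5 FP, 0 FN, 12 TP
        m = binary_metrics(ConfusionMatrix(tp=12, fn=0, tn=7, fp=5))
        assert round(m["specificity"], 3) == 0.583
        assert m["sensitivity"] == 1.0

    def test_with_augmentation_matrix_accuracy(self):
        # best model with GAN augmentation: 9 TN, 3 FP, 1 FN, 11 TP
        m = binary_metrics(ConfusionMatrix(tp=11, fn=1, tn=9, fp=3))
        assert round(m["accuracy"], 3) == 0.833

    def test_perfect_matrix(self):
        m = binary_metrics(ConfusionMatrix(tp=10, fn=0, tn=10, fp=0))
        assert m == {"sensitivity": 1.0, "specificity": 1.0, "accuracy": 1.0}

    def test_empty_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            binary_metrics(ConfusionMatrix(tp=5, fn=5, tn=0, fp=0))

    def test_matches_sklearn_on_random_predictions(self):
        from sklearn.metrics import accuracy_score, recall_score

        rng = np.random.default_rng(7)
        for _ in range(100):
            y = rng.integers(0, 2, size=50)
            p = rng.integers(0, 2, size=50)
            if len(set(y)) < 2:
                continue
            m = binary_metrics(ConfusionMatrix.from_predictions(y, p))
            assert m["accuracy"] == pytest.approx(accuracy_score(y, p))
            assert m["sensitivity"] == pytest.approx(recall_score(y, p, pos_label=1))
            assert m["specificity"] == pytest.approx(recall_score(y, p, pos_label=0))


class TestRoc:
    def test_perfect_separation(self):
        curve = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)

    def test_worked_example(self):
        curve = roc_auc([0.9, 0.3, 0.8, 0.1], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        curve = roc_auc(rng.uniform(size=40), rng.integers(0, 2, size=40))
        assert curve.points[0] == (0.0, 0.0)
        assert curve.points[-1] == (1.0, 1.0)
        xs = [p[0] for p in curve.points]
        ys = [p[1] for p in curve.points]
        assert all(b >= a for a, b in zip(xs, xs[1:]))
        assert all(b >= a for a, b in zip(ys, ys[1:]))

    def test_trapezoid_equals_concordance_on_tie_free_scores(self):
        rng = np.random.default_rng(2)
        scores = rng.permutation(np.linspace(0, 1, 30))
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        curve = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = np.mean([s > t for s in pos for t in neg])
        assert abs(curve.auc - conc) < 1e-12

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        scores = rng.uniform(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(3 * scores) + 1, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestProbabilityMap:
    @staticmethod
    def _records():
        return [
            PatchRecord("c", "s", 0, 0, 8, 1.0),
            PatchRecord("c", "s", 8, 0, 8, 1.0),
        ]

    def test_extreme_probabilities_use_colormap_ends(self):
        cmap = matplotlib.colormaps["jet"]
        hi = probability_to_color(1.0)
        lo = probability_to_color(0.0)
        np.testing.assert_array_equal(
            hi, [int(round(255 * v)) for v in cmap(1.0)[:3]]
        )
        np.testing.assert_array_equal(
            lo, [int(round(255 * v)) for v in cmap(0.0)[:3]]
        )

    def test_midpoint_probability_maps_to_colormap_midpoint(self):
        cmap = matplotlib.colormaps["jet"]
        np.testing.assert_array_equal(
            probability_to_color(0.5),
            [int(round(255 * v)) for v in cmap(0.5)[:3]],
        )

    def test_overlay_blends_and_leaves_rest_untouched(self):
        slide = np.full((16, 16, 3), 200, dtype=np.uint8)
        records = self._records()
        pmap = render_probability_map(slide, records, [1.0, 0.0], alpha=0.4)
        hi = probability_to_color(1.0).astype(float)
        expect = np.clip(np.rint(0.6 * 200 + 0.4 * hi), 0, 255)
        np.testing.assert_array_equal(pmap.overlay[0, 0], expect)
        np.testing.assert_array_equal(pmap.overlay[12, 4], [200, 200, 200])
        assert pmap.grid[0, 0] == 1.0 and pmap.grid[0, 1] == 0.0

    def test_out_of_bounds_record_rejected(self):
        slide = np.zeros((16, 16, 3), dtype=np.uint8)
        bad = [PatchRecord("c", "s", 12, 0, 8, 1.0)]
        with pytest.raises(ValueError):
            render_probability_map(slide, bad, [0.5])
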