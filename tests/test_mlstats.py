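"""Classifier comparison, pooled CV metrics and Tukey letter grouping."""

import numpy as np
import pytest

from mupadflow import (
    FAMILIES,
    ModelGrid,
    ProfileDataset,
    anova_tukey,
    compare_families,
    evaluate_report,
    grid_search_cv,
)
from mupadflow.mlstats import _compact_letters


def _separable_dataset(n_per_class=6, centers=(1.0, 5.0, 9.0), jitter=0.01, seed=0):
    rng = np.random.default_rng(seed)
    values, labels = [], []
    for cls, center in zip((0.1, 0.5, 1.0), centers):
        values.extend(center + jitter * rng.standard_normal(n_per_class))
        labels.extend([cls] * n_per_class)
    return ProfileDataset(
        matrix=np.array(values)[:, None],
        labels=np.array(labels),
        groups=np.arange(len(labels)) % n_per_class,
        feature_kind="fit_coefficient",
    )


class TestGridSearch:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_every_family_separates_wide_margin_classes(self, family):
        result = grid_search_cv(_separable_dataset(), family, seed=0)
        assert result.cv_accuracy_mean == 1.0
        assert result.cv_accuracy_sd == 0.0

    def test_single_point_grid_returns_that_point(self):
        grid = ModelGrid(family="knn", grid={"n_neighbors": [3]})
        result = grid_search_cv(_separable_dataset(), grid, seed=0)
        assert result.best_params == {"n_neighbors": 3}
        assert len(result.fold_accuracies) == 3

    def test_class_smaller_than_k_rejected(self):
        ds = _separable_dataset(n_per_class=2)
        with pytest.raises(ValueError, match="3-fold"):
            grid_search_cv(ds, "svm", k=3)

    def test_feature_order_permutation_is_irrelevant(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((24, 6))
        y = np.repeat([0.1, 0.5, 1.0], 8)
        x[:, 2] += 3 * np.searchsorted([0.1, 0.5, 1.0], y)
        ds = ProfileDataset(matrix=x, labels=y, groups=np.zeros(24))
        permuted = ProfileDataset(
            matrix=x[:, rng.permutation(6)], labels=y, groups=np.zeros(24)
        )
        a = grid_search_cv(ds, "gaussian_nb", seed=0)
        b = grid_search_cv(permuted, "gaussian_nb", seed=0)
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)

    def test_sample_order_permutation_keeps_separable_accuracy(self):
        ds = _separable_dataset()
        rng = np.random.default_rng(2)
        perm = rng.permutation(ds.n_samples)
        shuffled = ProfileDataset(
            matrix=ds.matrix[perm], labels=ds.labels[perm], groups=ds.groups[perm],
            feature_kind=ds.feature_kind,
        )
        assert grid_search_cv(shuffled, "svm", seed=0).cv_accuracy_mean == 1.0


class TestEvaluateReport:
    def test_perfect_classifier_metrics(self):
        report = evaluate_report(_separable_dataset(), "knn", {"n_neighbors": 3})
        assert np.all(report.confusion == np.diag([6, 6, 6]))
        assert report.accuracy == 1.0
        assert report.macro_precision == report.macro_recall == report.macro_f1 == 1.0

    def test_confusion_matrix_partitions_the_dataset(self):
        rng = np.random.default_rng(0)
        ds = ProfileDataset(
            matrix=rng.standard_normal((30, 2)),
            labels=np.repeat([0.1, 0.5, 1.0], 10),
            groups=np.zeros(30),
        )
        report = evaluate_report(ds, "decision_tree", {"max_depth": 3})
        assert report.confusion.sum() == 30
        np.testing.assert_array_equal(report.confusion.sum(axis=1), [10, 10, 10])

    def test_metrics_match_hand_computation_from_pooled_matrix(self):
        rng = np.random.default_rng(3)
        x = np.concatenate(
            [rng.normal(0, 1, 12), rng.normal(1.5, 1, 12), rng.normal(3, 1, 12)]
        )[:, None]
        ds = ProfileDataset(
            matrix=x, labels=np.repeat([0.1, 0.5, 1.0], 12), groups=np.zeros(36)
        )
        report = evaluate_report(ds, "lda", {})
        cm = report.confusion
        for j in range(3):
            col, row = cm[:, j].sum(), cm[j, :].sum()
            precision = cm[j, j] / col if col else 0.0
            recall = cm[j, j] / row if row else 0.0
            assert report.precision[j] == pytest.approx(precision)
            assert report.recall[j] == pytest.approx(recall)
            if precision + recall > 0:
                f1 = 2 * precision * recall / (precision + recall)
                assert report.f1[j] == pytest.approx(f1)
        assert report.accuracy == pytest.approx(np.trace(cm) / cm.sum())

    def test_compare_families_table_layout(self):
        table = compare_families(
            _separable_dataset(), families=("svm", "knn"), seed=0
        )
        assert list(table["family"]) == ["svm", "knn"]
        assert set(table.columns) >= {"cv_accuracy_mean", "cv_accuracy_sd", "best_params"}


class TestAnovaTukey:
    def test_zero_variance_separated_groups_get_distinct_letters(self):
        values = [1.0] * 4 + [2.0] * 4 + [3.0] * 4
        labels = [0.1] * 4 + [0.5] * 4 + [1.0] * 4
        result = anova_tukey(values, labels)
        assert result.letters == {0.1: "c", 0.5: "b", 1.0: "a"}
        assert result.all_distinct
        assert result.pairwise["reject"].all()

    def test_identical_zero_variance_groups_report_undefined_p(self):
        result = anova_tukey([5.0] * 9, [0.1] * 3 + [0.5] * 3 + [1.0] * 3)
        assert np.isnan(result.p) and np.isnan(result.f)
        assert not result.all_distinct
        letters = set(result.letters.values())
        assert len(letters) == 1  # everyone shares the single letter

    def test_f_statistic_matches_direct_mean_square_ratio(self):
        rng = np.random.default_rng(7)
        table = rng.normal([[0.0], [1.0], [2.0]], 1.0, size=(3, 5))
        values = table.ravel()
        labels = np.repeat([0.1, 0.5, 1.0], 5)
        grand = values.mean()
        ms_between = 5 * np.sum((table.mean(axis=1) - grand) ** 2) / (3 - 1)
        ms_within = np.sum((table - table.mean(axis=1, keepdims=True)) ** 2) / (15 - 3)
        result = anova_tukey(values, labels)
        assert result.f == pytest.approx(ms_between / ms_within)

    def test_null_calibration_shares_letters_most_of_the_time(self):
        shared = 0
        n_repeats = 40
        for seed in range(n_repeats):
            rng = np.random.default_rng(seed)
            values = rng.standard_normal(30)
            labels = np.repeat([0.1, 0.5, 1.0], 10)
            result = anova_tukey(values, labels, alpha=0.05)
            common = set.intersection(
                *(set(result.letters[g]) for g in result.groups)
            )
            shared += bool(common)
        # Tukey controls the familywise error at alpha, so ~95% of null
        # draws should leave all groups sharing a letter
        assert shared / n_repeats >= 0.85

    def test_compact_letters_chain_pattern(self):
        # extremes differ, the middle group differs from neither
        letters = _compact_letters(
            ["lo", "mid", "hi"],
            {"lo": 1.0, "mid": 2.0, "hi": 3.0},
            significant={frozenset(("lo", "hi"))},
        )
        assert letters == {"hi": "a", "mid": "ab", "lo": "b"}

    def test_degenerate_group_sizes_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([1.0, 2.0, 3.0], [0.1, 0.5, 1.0])
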