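"""Nested cross-validation: metrics, fold plans, grids, scrambling, importances."""

import numpy as np
import pytest

from dilimine.crossval import (
    RF_GRID,
    SVM_GRID,
    FoldPlan,
    build_fold_plan,
    extract_importance,
    grid_search_fit,
    make_model,
    nested_cv,
    similarity_response_analysis,
    y_scramble_baseline,
)
from dilimine.features import Scaler
from dilimine.metrics import (
    ConfusionMatrix,
    UndefinedMetricError,
    balanced_accuracy,
    mcc,
)
from dilimine.similarity import similarity_matrix


class TestBalancedAccuracy:
    def test_direct_substitution(self):
        assert balanced_accuracy(ConfusionMatrix(tp=7, fn=3, tn=8, fp=2)) == 0.75

    def test_perfect_and_constant(self):
        assert balanced_accuracy(ConfusionMatrix(tp=5, tn=5, fp=0, fn=0)) == 1.0
        # constant positive predictor: sens 1, spec 0
        assert balanced_accuracy(ConfusionMatrix(tp=5, tn=0, fp=5, fn=0)) == 0.5

    def test_formula_oracle_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            cm = ConfusionMatrix(int(tp), int(tn), int(fp), int(fn))
            if tp + fn == 0 or tn + fp == 0:
                with pytest.raises(UndefinedMetricError):
                    balanced_accuracy(cm)
                continue
            expected = (tp / (tp + fn) + tn / (tn + fp)) / 2
            assert balanced_accuracy(cm) == pytest.approx(expected)

    def test_class_absent_is_explicit_error(self):
        with pytest.raises(UndefinedMetricError):
            balanced_accuracy(ConfusionMatrix(tp=0, tn=3, fp=2, fn=0))

    def test_mcc_degenerate_margin_is_zero(self):
        assert mcc(ConfusionMatrix(tp=5, tn=0, fp=5, fn=0)) == 0.0


class TestGrids:
    def test_svm_grid_verbatim(self):
        assert SVM_GRID["C"] == [0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1]

    def test_rf_grid_verbatim(self):
        assert RF_GRID["max_depth"] == [10, 15, None]
        assert RF_GRID["min_samples_leaf"] == [1, 2, 3]
        assert RF_GRID["n_estimators"] == [100, 200, 300, 400, 500, 750, 1000]

    def test_model_construction(self):
        svm = make_model("svm", {"C": 0.1})
        assert svm.kernel == "linear" and svm.class_weight == "balanced"
        rf = make_model("rf", {"max_depth": 10, "min_samples_leaf": 1,
                               "n_estimators": 100}, seed=3)
        assert rf.class_weight == "balanced_subsample" and rf.bootstrap


class TestFoldPlan:
    def test_outer_partition_and_stratification(self, study_labels, study_clusters):
        plan = build_fold_plan(study_labels, study_clusters, seed=0)
        all_test = np.concatenate([te for _, te in plan.outer])
        assert sorted(all_test) == list(range(len(study_labels)))
        for _, te in plan.outer:
            # 200/200 labels: each outer fold holds exactly 20 positives
            assert (study_labels[te] == 1).sum() == 20

    def test_inner_groups_cluster_disjoint(self, study_labels, study_clusters):
        plan = build_fold_plan(study_labels, study_clusters, seed=0)
        for (tr, _), groups in zip(plan.outer, plan.inner_groups):
            clusters_tr = study_clusters[tr]
            for c in np.unique(clusters_tr):
                assert len(set(groups[clusters_tr == c])) == 1

    def test_inner_similarity_bound(self, study_fps, study_labels, study_clusters):
        """No inner train/validation pair exceeds Tanimoto 0.5."""
        plan = build_fold_plan(study_labels, study_clusters, seed=0)
        sim = similarity_matrix(study_fps)
        for (tr, _), groups in zip(plan.outer[:3], plan.inner_groups[:3]):
            for g in np.unique(groups):
                val_ids = tr[groups == g]
                train_ids = tr[groups != g]
                assert sim[np.ix_(val_ids, train_ids)].max() <= 0.5

    def test_two_clusters_two_groups_literal_loco(self):
        labels = np.array([1, 0, 1, 0])
        clusters = np.array([0, 0, 1, 1])
        plan = build_fold_plan(labels, clusters, seed=0, n_outer=2, n_inner=2)
        for groups, (tr, _) in zip(plan.inner_groups, plan.outer):
            for g in np.unique(groups):
                assert len(set(clusters[tr][groups == g])) == 1

    def test_oversized_cluster_fails(self):
        labels = np.array([1, 0] * 10)
        clusters = np.zeros(20, dtype=int)  # one cluster spans everything
        with pytest.raises(ValueError, match="80%"):
            build_fold_plan(labels, clusters, seed=0, n_outer=2)

    def test_seed_changes_outer_folds(self, study_labels, study_clusters):
        p0 = build_fold_plan(study_labels, study_clusters, seed=0)
        p1 = build_fold_plan(study_labels, study_clusters, seed=1)
        assert any(
            not np.array_equal(a[1], b[1]) for a, b in zip(p0.outer, p1.outer)
        )


@pytest.fixture(scope="module")
def separable_data():
    """Binary features where feature 0 fully separates the classes."""
    rng = np.random.default_rng(5)
    n = 80
    y = np.r_[np.ones(40, int), np.zeros(40, int)]
    x = (rng.random((n, 10)) < 0.3).astype(float)
    x[:, 0] = y
    clusters = np.arange(n) // 4  # 20 clusters of 4
    return x, y, clusters


class TestGridSearch:
    def test_single_point_grid(self, separable_data):
        x, y, clusters = separable_data
        plan = build_fold_plan(y, clusters, seed=0)
        res = grid_search_fit(
            x[plan.outer[0][0]], y[plan.outer[0][0]],
            plan.inner_groups[0], "svm", grid={"C": [0.3]},
        )
        assert res.best_params == {"C": 0.3}
        assert len(res.inner_scores) == 1

    def test_tie_break_prefers_smallest_c(self, separable_data):
        x, y, clusters = separable_data
        plan = build_fold_plan(y, clusters, seed=0)
        res = grid_search_fit(
            x[plan.outer[0][0]], y[plan.outer[0][0]],
            plan.inner_groups[0], "svm",
        )
        # perfectly separable: every C scores 1.0, so the first (smallest) wins
        assert res.best_params == {"C": 0.05}


class TestImportance:
    def test_rf_importances_sum_to_one(self, separable_data):
        x, y, _ = separable_data
        model = make_model(
            "rf", {"max_depth": 10, "min_samples_leaf": 1, "n_estimators": 100},
            seed=0,
        )
        model.fit(x, y)
        imp = extract_importance(model)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp >= 0).all()

    def test_separating_feature_dominates(self, separable_data):
        x, y, _ = separable_data
        svm = make_model("svm", {"C": 1})
        svm.fit(x, y)
        coefs = extract_importance(svm)
        assert np.argmax(np.abs(coefs)) == 0

    def test_constant_feature_zero_importance(self):
        rng = np.random.default_rng(0)
        x = rng.random((60, 4))
        x[:, 2] = 1.0
        y = (x[:, 0] > 0.5).astype(int)
        model = make_model(
            "rf", {"max_depth": 10, "min_samples_leaf": 1, "n_estimators": 50},
            seed=0,
        )
        model.fit(x, y)
        assert extract_importance(model)[2] == 0.0

    def test_nonlinear_kernel_unsupported(self):
        from sklearn.svm import SVC

        model = SVC(kernel="rbf")
        model.fit([[0.0], [1.0]], [0, 1])
        with pytest.raises(ValueError, match="linear"):
            extract_importance(model)


class TestNestedCV:
    def test_bitwise_reproducibility(self, separable_data):
        x, y, clusters = separable_data
        a = nested_cv(x, y, clusters, "svm", seed=3, grid={"C": [0.1, 1]})
        b = nested_cv(x, y, clusters, "svm", seed=3, grid={"C": [0.1, 1]})
        assert [f.cm for f in a.folds] == [f.cm for f in b.folds]
        assert [f.params for f in a.folds] == [f.params for f in b.folds]
        np.testing.assert_array_equal(a.importance_matrix(), b.importance_matrix())

    def test_separable_data_scores_high(self, separable_data):
        x, y, clusters = separable_data
        res = nested_cv(x, y, clusters, "svm", seed=3, grid={"C": [0.1]})
        assert res.mean_balanced_accuracy > 0.95

    def test_rf_path_runs(self, separable_data):
        x, y, clusters = separable_data
        res = nested_cv(
            x, y, clusters, "rf", seed=3,
            grid={"max_depth": [10], "min_samples_leaf": [1], "n_estimators": [50]},
        )
        assert res.mean_balanced_accuracy > 0.9
        assert res.importance_matrix().shape == (10, 10)

    def test_scramble_rerun_identical(self, separable_data):
        x, y, clusters = separable_data
        _, med_a = y_scramble_baseline(x, y, clusters, "svm", seed=5,
                                       grid={"C": [0.1]}, n_scrambles=2)
        _, med_b = y_scramble_baseline(x, y, clusters, "svm", seed=5,
                                       grid={"C": [0.1]}, n_scrambles=2)
        assert med_a == med_b

    def test_scaler_never_sees_test_rows(self, separable_data, monkeypatch):
        """Instrumented no-leakage check: every scaler fit uses a strict
        subset of a training fold's rows, never the full dataset."""
        x, y, clusters = separable_data
        x = x + 0.01 * np.arange(len(y))[:, None]  # make rows identifiable
        plan = build_fold_plan(y, clusters, seed=0)
        seen = []
        original = Scaler.fit

        def recording_fit(self, matrix):
            seen.append(frozenset(np.round(matrix.values[:, 0] % 1, 6)))
            return original(self, matrix)

        monkeypatch.setattr(Scaler, "fit", recording_fit)
        nested_cv(x.astype(float), y, clusters, "svm", seed=0,
                  grid={"C": [0.1]}, plan=plan, scale=True)
        assert seen, "scaling path was not exercised"
        train_sets = [
            frozenset(np.round(x[tr, 0] % 1, 6)) for tr, _ in plan.outer
        ]
        for rows in seen:
            assert any(rows <= t for t in train_sets)
            assert len(rows) < len(y)


class TestSimilarityResponse:
    def test_bins_partition_and_conserve(self, separable_data):
        x, y, _ = separable_data
        fps = (x > 0).astype(int)
        table = similarity_response_analysis(
            fps, y, lambda: make_model("svm", {"C": 0.1})
        )
        assert table["n"].sum() == len(y)
        assert table["bin_low"].iloc[0] == 0.0
        assert table["bin_high"].iloc[-1] == pytest.approx(1.0)

    def test_near_duplicates_top_bin_perfect(self):
        rng = np.random.default_rng(2)
        base = (rng.random((6, 60)) < 0.4).astype(int)
        # planted near-duplicate pairs sharing labels
        fps = np.repeat(base, 3, axis=0)
        flip = rng.integers(0, 60, size=len(fps))
        for i, j in enumerate(flip):
            if i % 3:
                fps[i, j] ^= 1
        y = np.repeat(np.r_[np.ones(3, int), np.zeros(3, int)], 3)
        table = similarity_response_analysis(
            fps, y, lambda: make_model("svm", {"C": 1})
        )
        top = table[(table["n"] > 0)].iloc[-1]
        assert top["bin_low"] >= 0.5
        assert top["rate"] == 1.0

    def test_single_compound_bin_flagged(self, separable_data):
        x, y, _ = separable_data
        fps = (x > 0).astype(int)
        table = similarity_response_analysis(
            fps, y, lambda: make_model("svm", {"C": 0.1})
        )
        ones = table[table["n"] == 1]
        assert ones.empty or ones["single_compound"].all()
        empty = table[table["n"] == 0]
        assert empty["rate"].isna().all()

    def test_too_small_dataset_fails(self):
        with pytest.raises(ValueError, match="at least 6"):
            similarity_response_analysis(
                np.ones((4, 8), int), np.array([0, 1, 0, 1]),
                lambda: make_model("svm", {"C": 1}),
            )
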