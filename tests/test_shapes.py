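import numpy as np
import pytest

from amylv import shapes
from amylv.synthetic import CohortSpec, ShapeDataset, generate_shape_cohort
from amylv.template import LVTemplateSpec, generate_template


def small_cohort(sep=True, seed=0, n_h=8, n_a=6):
    """Fast cohort; well separated when sep else overlapping classes."""
    spec = CohortSpec(
        n_healthy=n_h, n_amyloid=n_a,
        healthy_thickness_median=0.77,
        amyloid_thickness_median=1.11 if sep else 0.77,
        thickness_sd=0.03 if sep else 0.08,
        size_sd=0.03, seed=seed, n_long=12,
    )
    return generate_shape_cohort(spec)


class TestAssembleMatrix:
    def test_row_per_mesh_fixed_column_order(self):
        ds = small_cohort()
        meshes = ds.meta["meshes"]
        out = shapes.assemble_matrix(meshes, ds.labels)
        np.testing.assert_array_equal(out.X, ds.X)

    def test_permuting_subjects_permutes_rows_only(self):
        ds = small_cohort()
        meshes = ds.meta["meshes"]
        perm = np.random.default_rng(1).permutation(len(meshes))
        out = shapes.assemble_matrix([meshes[i] for i in perm], ds.labels[perm])
        np.testing.assert_array_equal(out.X, ds.X[perm])

    def test_duplicated_mesh_gives_identical_rows(self):
        ds = small_cohort()
        m = ds.meta["meshes"][0]
        out = shapes.assemble_matrix([m, m], ["healthy", "healthy"])
        np.testing.assert_array_equal(out.X[0], out.X[1])

    def test_vertex_count_mismatch_rejected(self):
        ds = small_cohort()
        other = generate_template(LVTemplateSpec(n_long=10, n_circ=20, n_trans=1))
        with pytest.raises(ValueError, match="mismatch"):
            shapes.assemble_matrix([ds.meta["meshes"][0], other], ["healthy", "healthy"])


class TestPCA:
    def test_identical_shapes_have_zero_eigenvalues(self):
        ds = small_cohort()
        X = np.tile(ds.X[0], (5, 1))
        flat = ShapeDataset(X, np.array(["healthy"] * 5),
                            np.arange(5).astype(str), np.array(["baseline"] * 5))
        model = shapes.fit_pca(flat, 3)
        np.testing.assert_allclose(model.eigenvalues, 0.0, atol=1e-12)

    def test_pure_size_cohort_loads_on_one_mode(self):
        base = small_cohort().meta["meshes"][0]
        scales = np.linspace(0.9, 1.1, 9)
        X = np.array([(s * base.points)[
            np.concatenate([base.endo_nodes, base.epi_nodes])].reshape(-1)
            for s in scales])
        ds = ShapeDataset(X, np.array(["healthy"] * 9),
                          np.arange(9).astype(str), np.array(["baseline"] * 9))
        model = shapes.fit_pca(ds, 3)
        explained = model.eigenvalues / model.eigenvalues.sum()
        assert explained[0] > 0.95
        scores = (X - model.mean_shape) @ model.components[0]
        assert abs(np.corrcoef(scores, scales)[0, 1]) > 0.999

    def test_full_reconstruction_is_exact(self):
        ds = small_cohort(n_h=5, n_a=3)
        model = shapes.fit_pca(ds, ds.n_subjects - 1)
        Z = (ds.X - model.mean_shape) @ model.components.T
        recon = model.mean_shape + Z @ model.components
        np.testing.assert_allclose(recon, ds.X, atol=1e-8)

    def test_eigenvalues_non_increasing_components_orthonormal(self):
        ds = small_cohort()
        model = shapes.fit_pca(ds, 5)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-10)

    def test_mode_shapes_are_symmetric_about_the_mean(self):
        ds = small_cohort()
        model = shapes.fit_pca(ds, 2)
        plus, minus = shapes.mode_shapes(model, 0, scale=1.5)
        np.testing.assert_allclose(
            (plus + minus).reshape(-1) / 2.0, model.mean_shape, atol=1e-10
        )

    def test_component_count_validated(self):
        ds = small_cohort(n_h=4, n_a=3)
        with pytest.raises(ValueError, match="n_components"):
            shapes.fit_pca(ds, 100)


class TestLOOCV:
    def test_separable_cohort_is_perfectly_classified(self):
        ds = small_cohort(sep=True)
        for method in ("lda", "kernel_svm"):
            m = shapes.loocv_classify(ds, method=method)
            assert (m.sensitivity, m.specificity, m.f1) == (1.0, 1.0, 1.0)

    def test_fold_count_equals_subject_count(self):
        ds = small_cohort()
        m = shapes.loocv_classify(ds, method="lda")
        assert m.TP + m.FP + m.FN + m.TN == ds.n_subjects

    def test_shuffled_labels_drop_to_chance(self):
        ds = small_cohort(sep=True)
        rng = np.random.default_rng(0)
        f1s = []
        for _ in range(20):
            shuffled = ShapeDataset(
                ds.X, rng.permutation(ds.labels), ds.subject_ids, ds.scans
            )
            try:
                m = shapes.loocv_classify(shuffled, method="lda")
                f1s.append(m.f1)
            except ValueError:
                pass  # a fold lost a class; skip that shuffle
        assert np.mean(f1s) < 0.55

    def test_subject_order_invariance(self):
        ds = small_cohort()
        perm = np.random.default_rng(3).permutation(ds.n_subjects)
        m1 = shapes.loocv_classify(ds, method="lda")
        m2 = shapes.loocv_classify(ds.rows(perm), method="lda")
        assert (m1.TP, m1.FP, m1.FN, m1.TN) == (m2.TP, m2.FP, m2.FN, m2.TN)

    def test_single_class_dataset_rejected(self):
        ds = small_cohort()
        flat = ShapeDataset(ds.X, np.array(["healthy"] * ds.n_subjects),
                            ds.subject_ids, ds.scans)
        with pytest.raises(ValueError, match="two classes"):
            shapes.loocv_classify(flat)


class TestF1:
    def test_reconstructed_reference_counts(self):
        # LDA sensitivity 0.71 = 5/7 and specificity 0.92 = 24/26 imply
        # TP=5, FN=2, FP=2 and F1 = 10/14 = 0.71
        assert shapes.f1_score(5, 2, 2) == pytest.approx(10 / 14)

    def test_perfect_and_null_classifiers(self):
        assert shapes.f1_score(3, 0, 0) == 1.0
        assert shapes.f1_score(0, 2, 3) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            shapes.f1_score(0, 0, 0)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import f1_score as sk_f1

        y_true = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        y_pred = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        assert shapes.f1_score(tp, fp, fn) == pytest.approx(
            sk_f1(y_true, y_pred)
        )


class TestLDADistance:
    def test_subject_at_the_healthy_mean_scores_zero(self):
        ds = small_cohort(n_h=9, n_a=4)
        healthy = ds.X[ds.labels == "healthy"]
        X = np.vstack([ds.X, healthy[:-1].mean(axis=0, keepdims=True)])
        labels = np.append(ds.labels, "healthy")
        aug = ShapeDataset(X, labels, np.arange(len(X)).astype(str),
                           np.array(["baseline"] * len(X)))
        # train excludes the appended subject; it sits at the mean of the
        # remaining healthy rows only if those rows average to it
        d = shapes.lda_distance(aug, len(X) - 1)
        # the appended row is the mean of healthy[:-1]; training healthy
        # rows are healthy[:-1] + healthy[-1]; allow the small offset
        assert abs(d) < 1.5

    def test_separated_classes_share_a_distance_sign(self):
        ds = small_cohort(sep=True)
        idx = np.flatnonzero(ds.labels == "amyloid")
        dists = [shapes.lda_distance(ds, int(i)) for i in idx]
        assert all(d > 0 for d in dists)

    def test_trajectory_direction(self):
        assert shapes.shape_trajectory(2.0, 1.2) == "down"
        assert shapes.shape_trajectory(1.2, 2.0) == "up"

    def test_rigid_transform_of_all_meshes_preserves_distances(self):
        ds = small_cohort(n_h=6, n_a=4)
        from conftest import random_rotation

        R = random_rotation(np.random.default_rng(4))
        t = np.array([1.0, -2.0, 0.5])
        Xr = (ds.X.reshape(ds.n_subjects, -1, 3) @ R.T + t).reshape(ds.n_subjects, -1)
        moved = ShapeDataset(Xr, ds.labels, ds.subject_ids, ds.scans)
        for i in (0, len(ds.X) - 1):
            assert shapes.lda_distance(moved, i) == pytest.approx(
                shapes.lda_distance(ds, i), abs=1e-6
            )


class TestMoodsMedianTest:
    def test_identical_groups_are_uninformative(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert shapes.moods_median_test(a, a) > 0.5

    def test_constant_data_returns_one(self):
        assert shapes.moods_median_test([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_clear_shift_at_cohort_sizes(self):
        # mirrors the 26 vs 7 healthy/amyloid comparison with a shift much
        # larger than the spread
        rng = np.random.default_rng(0)
        rejected = 0
        for rep in range(10):
            a = 0.77 + 0.05 * rng.standard_normal(26)
            b = 1.11 + 0.05 * rng.standard_normal(7)
            rejected += shapes.moods_median_test(a, b) < 0.05
        assert rejected >= 9

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(5)
        a = rng.random(15)
        b = rng.random(9) + 0.3
        p0 = shapes.moods_median_test(a, b)
        assert shapes.moods_median_test(np.exp(a), np.exp(b)) == pytest.approx(p0)
        assert shapes.moods_median_test(a**3, b**3) == pytest.approx(p0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            shapes.moods_median_test([], [1.0])
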