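"""Discriminant fitting, projection, classification, cross-validation."""

import numpy as np
import pytest

from hsslda import (
    DiscriminantModel,
    LabelVector,
    classify,
    crossvalidate,
    fit_lda,
    transform,
)
from hsslda import synthetic

from conftest import labels_of, matrix_of


def dense_geneig_oracle(X, codes, k):
    """Independent oracle: scatter matrices assembled from the definition and
    solved as a dense non-symmetric eigenproblem of Sw^-1 Sb."""
    n, p = X.shape
    counts = np.bincount(codes, minlength=k)
    pri = counts / n
    means = np.vstack([X[codes == c].mean(axis=0) for c in range(k)])
    xbar = pri @ means
    Sw = sum(
        (X[codes == c] - means[c]).T @ (X[codes == c] - means[c]) for c in range(k)
    ) / (n - k)
    Sb = sum(
        pri[c] * np.outer(means[c] - xbar, means[c] - xbar) for c in range(k)
    )
    evals, evecs = np.linalg.eig(np.linalg.solve(Sw, Sb))
    order = np.argsort(evals.real)[::-1][: k - 1]
    W = evecs[:, order].real
    return (X - xbar) @ W


def random_problem(rng, n=200, p=6, k=3, spread=2.0):
    X = rng.normal(size=(n, p))
    codes = rng.integers(k, size=n)
    X[:, 0] += spread * codes
    X[:, 1] -= spread * (codes == 1)
    return matrix_of(X), labels_of([f"g{c}" for c in codes], [f"g{c}" for c in range(k)])


class TestFit:
    def test_k_minus_one_axes(self):
        m, y = synthetic.make_blobs(
            synthetic.BlobSpec(k=5, p_informative=4, p_noise=3,
                               class_sizes=[40] * 5, seed=0)
        )
        model = fit_lda(m, y)
        assert model.n_axes == 4  # k - 1 discriminants for k = 5

    def test_axes_capped_by_feature_count(self):
        m, y = synthetic.make_blobs(
            synthetic.BlobSpec(k=5, p_informative=2, p_noise=0,
                               class_sizes=[40] * 5, seed=0)
        )
        assert fit_lda(m, y).n_axes == 2  # min(k-1, p_sub)

    def test_informative_feature_dominates_loadings(self, rng):
        n = 2000
        codes = rng.integers(2, size=n)
        X = np.column_stack([rng.normal(size=n) + 5 * codes, rng.normal(size=n)])
        model = fit_lda(matrix_of(X), labels_of([f"g{c}" for c in codes]))
        w = np.abs(model.scalings[:, 0])
        assert w[0] > 20 * w[1]

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        m, y = random_problem(rng)
        ours = transform(fit_lda(m, y), m).coords
        theirs = dense_geneig_oracle(m.values, y.codes(), y.n_classes)
        for j in range(ours.shape[1]):
            r = np.corrcoef(ours[:, j], theirs[:, j])[0, 1]
            assert abs(r) > 0.999

    def test_matches_sklearn_reference(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        m, y = random_problem(rng)
        ours = transform(fit_lda(m, y), m).coords
        ref = LinearDiscriminantAnalysis(solver="eigen").fit(
            m.values, y.codes()
        ).transform(m.values)
        for j in range(ours.shape[1]):
            r = np.corrcoef(ours[:, j], ref[:, j])[0, 1]
            assert abs(r) > 0.999

    def test_eigenvalues_non_increasing_and_priors_sum_to_one(self, rng):
        m, y = random_problem(rng)
        model = fit_lda(m, y)
        assert (np.diff(model.eigenvalues) <= 1e-12).all()
        assert model.priors.sum() == pytest.approx(1.0)

    def test_within_class_covariance_spherized(self, rng):
        m, y = random_problem(rng, n=600)
        model = fit_lda(m, y)
        z = transform(model, m).coords
        codes = y.codes()
        pooled = sum(
            (z[codes == c] - z[codes == c].mean(0)).T
            @ (z[codes == c] - z[codes == c].mean(0))
            for c in range(y.n_classes)
        ) / (len(z) - y.n_classes)
        np.testing.assert_allclose(pooled, np.eye(model.n_axes), atol=1e-8)

    def test_singleton_class_errors(self):
        m = matrix_of(np.arange(8.0).reshape(4, 2))
        y = labels_of(["a", "a", "a", "b"])
        with pytest.raises(ValueError, match="b"):
            fit_lda(m, y)

    def test_collinear_feature_triggers_ridge_and_preserves_embedding(self, rng):
        m, y = random_problem(rng)
        clean = fit_lda(m, y)
        dup_vals = np.column_stack([m.values, m.values[:, 0]])
        dup = matrix_of(dup_vals, features=m.feature_names + ["dup"])
        degraded = fit_lda(dup, y)
        assert degraded.ridge > 0 and clean.ridge == 0
        a = transform(clean, m).coords
        b = transform(degraded, dup).coords
        for j in range(2):
            assert abs(np.corrcoef(a[:, j], b[:, j])[0, 1]) > 0.99

    def test_row_permutation_invariance(self, rng):
        m, y = random_problem(rng)
        perm = rng.permutation(m.n_cells)
        zp = transform(fit_lda(m.select_cells(perm), y.select(perm)), m).coords
        z = transform(fit_lda(m, y), m).coords
        np.testing.assert_allclose(z, zp, atol=1e-8)

    def test_deterministic_refit(self, rng):
        m, y = random_problem(rng)
        a, b = fit_lda(m, y), fit_lda(m, y)
        np.testing.assert_array_equal(a.scalings, b.scalings)

    def test_json_round_trip(self, tmp_path, rng):
        m, y = random_problem(rng)
        model = fit_lda(m, y)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = DiscriminantModel.from_json(path)
        np.testing.assert_allclose(back.scalings, model.scalings, rtol=1e-15)
        assert back.feature_subset == model.feature_subset
        np.testing.assert_allclose(
            transform(back, m).coords, transform(model, m).coords, atol=1e-12
        )


class TestTransform:
    def test_training_projection_reproduces_fit_coordinates(self, blobs500):
        m, y = blobs500
        model = fit_lda(m, y)
        z1 = transform(model, m).coords
        z2 = transform(model, m).coords
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_global_mean_maps_to_origin(self, blobs500):
        m, y = blobs500
        model = fit_lda(m, y)
        mean_cell = matrix_of(
            model.global_means[None, :], features=model.feature_subset
        )
        z = transform(model, mean_cell).coords
        np.testing.assert_allclose(z, 0.0, atol=1e-10)

    def test_duplicated_cell_projects_identically(self, blobs500):
        m, y = blobs500
        model = fit_lda(m, y)
        two = matrix_of(
            np.vstack([m.values[0], m.values[0]]), features=m.feature_names
        )
        z = transform(model, two).coords
        np.testing.assert_array_equal(z[0], z[1])

    def test_extra_features_ignored_missing_listed(self, blobs500):
        m, y = blobs500
        model = fit_lda(m, y, features=["inf_1", "inf_2"])
        z_sub = transform(model, m.select_features(["inf_1", "inf_2"]))
        z_all = transform(model, m)  # extra columns present but unused
        np.testing.assert_array_equal(z_sub.coords, z_all.coords)
        with pytest.raises(KeyError, match="inf_2"):
            transform(model, m.select_features(["inf_1", "noise_1"]))


class TestClassify:
    def test_separable_training_data_recovered(self, blobs500):
        m, y = blobs500
        model = fit_lda(m, y)
        pred = classify(model, m)
        assert (pred.labels == y.labels).mean() > 0.99

    def test_cell_at_centroid_assigned_that_class(self, blobs500):
        m, y = blobs500
        model = fit_lda(m, y, priors="uniform")
        # invert a centroid back to feature space via least squares
        for c in range(y.n_classes):
            x = model.global_means + np.linalg.lstsq(
                model.scalings.T, model.class_centroids[c], rcond=None
            )[0]
            cell = matrix_of(x[None, :], features=model.feature_subset)
            assert classify(model, cell).labels[0] == y.classes[c]

    def test_agrees_with_mahalanobis_oracle(self, rng):
        """Direct per-class scoring in feature space: pooled covariance,
        Mahalanobis distance to each class mean plus log prior."""
        m, y = random_problem(rng, n=300, k=3, spread=1.0)  # overlapping classes
        model = fit_lda(m, y)
        pred = classify(model, m).labels

        X, codes, k = m.values, y.codes(), y.n_classes
        counts = np.bincount(codes, minlength=k)
        means = np.vstack([X[codes == c].mean(axis=0) for c in range(k)])
        Sw = sum(
            (X[codes == c] - means[c]).T @ (X[codes == c] - means[c])
            for c in range(k)
        ) / (len(X) - k)
        Swi = np.linalg.inv(Sw)
        idx = rng.choice(len(X), size=100, replace=False)
        for i in idx:
            scores = [
                -0.5 * (X[i] - means[c]) @ Swi @ (X[i] - means[c])
                + np.log(counts[c] / len(X))
                for c in range(k)
            ]
            assert pred[i] == y.classes[int(np.argmax(scores))]

    def test_tie_breaks_to_first_class(self):
        # two identical classes: every score ties, first class must win
        vals = np.array([[0.0, 0], [1, 1], [0, 0], [1, 1], [0.5, 0.2], [0.6, 0.9]])
        m = matrix_of(vals)
        y = labels_of(["a", "a", "b", "b", "a", "b"], ["a", "b"])
        model = fit_lda(m, y)
        model.class_centroids[1] = model.class_centroids[0]
        model.priors[:] = 0.5
        pred = classify(model, m)
        assert set(pred.labels) == {"a"}


class TestCrossValidate:
    def test_separable_blobs_perfect_accuracy(self, blobs500):
        m, y = blobs500
        cv = crossvalidate(m, y, folds=5, seed=0)
        assert cv.accuracy > 0.99
        assert cv.confusion.to_numpy().sum() == m.n_cells

    def test_shuffled_labels_chance_level(self, rng):
        n, k = 1500, 5
        m = matrix_of(rng.normal(size=(n, 4)))
        y = labels_of(
            [f"g{c}" for c in rng.integers(k, size=n)],
            [f"g{c}" for c in range(k)],
        )
        cv = crossvalidate(m, y, folds=5, seed=1)
        assert cv.accuracy == pytest.approx(1 / k, abs=0.06)

    def test_cyclic_confusion_concentrates_on_adjacent_phases(self, cycle2000):
        m, y, _ = cycle2000
        cv = crossvalidate(m, y, folds=10, seed=0)
        assert cv.n_errors > 0
        assert cv.adjacent_error_fraction >= 0.95

    def test_class_smaller_than_folds_errors(self):
        vals = np.random.default_rng(0).normal(size=(20, 3))
        y = labels_of(["a"] * 17 + ["b"] * 3)
        with pytest.raises(ValueError, match="folds"):
            crossvalidate(matrix_of(vals), y, folds=5, seed=0)
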