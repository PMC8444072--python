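import numpy as np
import pytest

from orthomoments.features import (
    fit_feature_space,
    lda_fit,
    lda_project,
    pca_project,
    qmode_pca_fit,
    t_select,
    t_statistics,
    transform_feature_space,
    zscore_apply,
    zscore_fit_apply,
)


class TestZScore:
    def test_hand_column(self):
        Z, _ = zscore_fit_apply(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Z.ravel(), [-1.0, 0.0, 1.0])  # sample sd = 1

    def test_constant_column_maps_to_zero(self):
        Z, _ = zscore_fit_apply(np.column_stack([np.ones(4), np.arange(4.0)]))
        assert np.all(Z[:, 0] == 0.0)

    def test_idempotent_on_standardized_data(self, rng):
        X = rng.normal(size=(50, 3))
        Z1, _ = zscore_fit_apply(X)
        Z2, _ = zscore_fit_apply(Z1)
        np.testing.assert_allclose(Z1, Z2, atol=1e-12)

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            zscore_fit_apply(np.ones((1, 3)))


class TestTSelect:
    def test_hand_pooled_t(self):
        X = np.column_stack([[0.0, 1, 2, 3], [1.0, 0, 0, 1]])
        labels = np.array(["A", "A", "B", "B"])
        t = t_statistics(X, labels)
        np.testing.assert_allclose(t[0], -2.0 / np.sqrt(0.5), atol=1e-12)
        assert t[1] == 0.0
        assert list(t_select(X, labels, fraction=0.5)) == [0]

    def test_ceiling_count(self, rng):
        X = rng.normal(size=(8, 250))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        assert len(t_select(X, labels, fraction=0.01)) == 3  # ceil(2.5)

    def test_zero_signal_never_beats_signal(self, rng):
        n = 20
        labels = np.array(["a"] * 10 + ["b"] * 10)
        flat = np.tile([0.5, 1.0], 10)[:n]  # same in both classes
        signal = np.r_[np.zeros(10), np.ones(10)] + rng.normal(0, 0.1, n)
        X = np.column_stack([flat, signal])
        assert list(t_select(X, labels, fraction=0.5)) == [1]

    def test_scaling_invariance_after_zscore(self, rng):
        X = rng.normal(size=(12, 30))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        Z, _ = zscore_fit_apply(X)
        Z_scaled, _ = zscore_fit_apply(X * 7.5)
        assert list(t_select(Z, labels, 0.1)) == list(t_select(Z_scaled, labels, 0.1))

    def test_small_class_rejected(self):
        X = np.zeros((3, 4))
        with pytest.raises(ValueError):
            t_select(X, np.array(["a", "a", "b"]))


class TestQModePCA:
    def test_rank_one_data(self):
        direction = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.outer([0.0, 1.0, 2.0, 3.0], direction)
        model = qmode_pca_fit(X, beta=0.5)
        assert model.k == 1
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_total_variance_preserved(self, rng):
        X = rng.normal(size=(10, 40))
        model = qmode_pca_fit(X, beta=1.0)
        centered = X - X.mean(axis=0)
        np.testing.assert_allclose(
            (model.scores**2).sum(), (centered**2).sum(), rtol=1e-10
        )

    def test_cumulative_threshold_rule(self):
        # spectrum with ratios 0.6 / 0.3 / 0.1 -> beta 0.9 keeps 2
        rng = np.random.default_rng(5)
        basis = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        scores = rng.normal(size=(500, 3))
        scores = (scores - scores.mean(0)) / scores.std(0, ddof=1)
        scores = np.linalg.qr(scores)[0] * np.sqrt(500)
        X = scores @ np.diag([np.sqrt(6.0), np.sqrt(3.0), 1.0]) @ basis.T
        model = qmode_pca_fit(X, beta=0.9)
        np.testing.assert_allclose(
            model.explained_variance_ratio, [0.6, 0.3, 0.1], atol=1e-8
        )
        assert model.k == 2

    def test_projection_reproduces_training_scores(self, rng):
        X = rng.normal(size=(9, 25))
        model = qmode_pca_fit(X, beta=0.95)
        np.testing.assert_allclose(
            pca_project(X, model), model.scores[:, : model.k], atol=1e-10
        )

    def test_mean_row_maps_to_origin(self, rng):
        X = rng.normal(size=(7, 12))
        model = qmode_pca_fit(X, beta=0.95)
        np.testing.assert_allclose(pca_project(X.mean(axis=0), model), 0.0, atol=1e-10)

    def test_output_shape_contract(self, rng):
        X = rng.normal(size=(8, 20))
        model = qmode_pca_fit(X, n_components=3)
        assert pca_project(rng.normal(size=(5, 20)), model).shape == (5, 3)

    def test_column_mismatch_rejected(self, rng):
        model = qmode_pca_fit(rng.normal(size=(5, 6)), beta=0.95)
        with pytest.raises(ValueError):
            pca_project(np.zeros((2, 7)), model)


class TestLDA:
    def test_two_separated_1d_classes(self):
        V = np.array([[0.0], [0.2], [5.0], [5.1]])
        labels = np.array(["a", "a", "b", "b"])
        lda = lda_fit(V, labels)
        assert lda.weights.shape == (1, 1)
        D = lda_project(V, lda)
        means = [D[labels == c].mean() for c in ("a", "b")]
        assert abs(means[0] - means[1]) > 5 * D[labels == "a"].std(ddof=1)

    def test_sample_order_invariance(self, rng):
        V = rng.normal(size=(20, 4))
        labels = np.array(["a", "b"] * 10)
        perm = rng.permutation(20)
        A1 = lda_fit(V, labels).weights
        A2 = lda_fit(V[perm], labels[perm]).weights
        np.testing.assert_allclose(A1, A2, atol=1e-8)

    def test_collinear_class_means_concentrate_on_first_axis(self, rng):
        # three classes with means on a line: one discriminant carries
        # all separation, the second explains none
        means = np.array([[0.0, 0.0], [2.0, 1.0], [4.0, 2.0]])
        V = np.vstack([m + rng.normal(0, 0.2, size=(40, 2)) for m in means])
        labels = np.repeat(["a", "b", "c"], 40)
        lda = lda_fit(V, labels)
        D = lda_project(V, lda)
        centroids = np.array([D[labels == c].mean(axis=0) for c in ("a", "b", "c")])
        between = centroids.var(axis=0)
        assert between[0] > 100 * between[1]

    def test_identity_weights_pass_through(self, rng):
        scores = rng.normal(size=(10, 2))
        np.testing.assert_array_equal(lda_project(scores, np.eye(2)), scores)

    def test_projection_shape(self, rng):
        scores = rng.normal(size=(10, 4))
        A = rng.normal(size=(4, 2))
        assert lda_project(scores, A).shape == (10, 2)

    def test_singleton_class_rejected(self):
        V = np.zeros((3, 2))
        with pytest.raises(ValueError, match="b"):
            lda_fit(V, np.array(["a", "a", "b"]))


class TestFullPipeline:
    def test_deterministic_fit(self, rng):
        X = rng.normal(size=(24, 100))
        labels = np.array(["a"] * 12 + ["b"] * 12)
        m1 = fit_feature_space(X, labels, select_fraction=0.05, beta=0.9)
        m2 = fit_feature_space(X, labels, select_fraction=0.05, beta=0.9)
        np.testing.assert_array_equal(m1.lda.weights, m2.lda.weights)
        np.testing.assert_array_equal(m1.selected, m2.selected)

    def test_heldout_class_means_match_training(self, rng):
        # draws from the training distribution land around the training
        # class means in discriminant space
        def draw(n):
            labels = np.repeat(["a", "b"], n)
            X = rng.normal(size=(2 * n, 50))
            X[labels == "b", :5] += 3.0
            return X, labels

        X, labels = draw(40)
        model = fit_feature_space(X, labels, beta=0.95)
        D_train = transform_feature_space(X, model)
        Xh, lh = draw(40)
        D_held = transform_feature_space(Xh, model)
        for c in ("a", "b"):
            gap = np.abs(D_train[labels == c].mean(0) - D_held[lh == c].mean(0))
            spread = D_train[labels == c].std(0, ddof=1)
            assert np.all(gap < spread)
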