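"""Pareto scaling, PCA, NIPALS PLS-DA, VIP, cross-validation and the
label-permutation test."""

import numpy as np
import pytest

from afnmr import (
    PLSDAModel,
    back_transform,
    cross_validate,
    pareto_scale,
    pca_fit,
    permutation_test,
    plsda_fit,
    plsda_predict,
    vip_scores,
)


def _two_group_data(n0=12, n1=8, p=6, delta=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n0 + n1, p))
    X[n0:, :3] += delta
    labels = np.array(["term"] * n0 + ["preterm"] * n1)
    return X, labels


class TestParetoScaling:
    def test_constant_column_centered_and_flagged(self):
        X = np.column_stack([np.full(5, 3.0), np.arange(5.0)])
        s = pareto_scale(X)
        assert np.allclose(s.values[:, 0], 0.0)
        assert s.zero_variance.tolist() == [True, False]

    def test_scaled_sd_is_sqrt_of_original(self):
        X = np.array([[0.0], [4.0 * np.sqrt(2.0)]])  # sample sd = 4
        s = pareto_scale(X)
        assert np.std(s.values[:, 0], ddof=1) == pytest.approx(2.0)

    def test_round_trip_is_exact(self):
        rng = np.random.default_rng(2)
        X = rng.normal(3.0, 2.0, size=(9, 5))
        assert np.allclose(back_transform(pareto_scale(X)), X, atol=1e-12)


class TestPCA:
    def test_rank_one_data_fully_explained_by_first_component(self):
        t = np.linspace(-1, 1, 10)
        X = np.outer(t, [1.0, -2.0, 0.5])
        model = pca_fit(pareto_scale(X), ncomp=2)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_covariance_is_diagonal(self):
        rng = np.random.default_rng(3)
        model = pca_fit(pareto_scale(rng.normal(size=(12, 7))), ncomp=3)
        c = model.scores.T @ model.scores
        off = c - np.diag(np.diag(c))
        assert np.max(np.abs(off)) < 1e-9

    def test_explained_fractions_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 6))
        s = pareto_scale(X)
        model = pca_fit(s, ncomp=4)
        # independent oracle: eigenvalues of the covariance matrix
        Xc = s.values - s.values.mean(axis=0)
        ev = np.linalg.eigvalsh(Xc.T @ Xc)[::-1]
        expected = ev[:4] / ev.sum()
        assert np.allclose(model.explained_variance_fraction, expected, atol=1e-9)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca_fit(pareto_scale(np.random.default_rng(0).normal(size=(4, 3))), 4)


class TestPLSDA:
    def test_label_collinear_feature_fits_exactly(self):
        y01 = np.array([0.0] * 6 + [1.0] * 6)
        X = np.column_stack([y01, -0.5 * y01])  # both collinear with y
        model = plsda_fit(pareto_scale(X), ["a"] * 6 + ["b"] * 6, ncomp=1)
        assert model.r2y_cum > 0.999

    def test_score_vectors_are_mutually_orthogonal(self):
        X, labels = _two_group_data()
        model = plsda_fit(pareto_scale(X), labels, ncomp=3)
        g = model.scores.T @ model.scores
        off = g - np.diag(np.diag(g))
        assert np.max(np.abs(off)) < 1e-8

    def test_single_class_rejected(self):
        X, _ = _two_group_data()
        with pytest.raises(ValueError):
            plsda_fit(pareto_scale(X), ["same"] * X.shape[0])

    def test_r2_matches_reference_pls_implementation(self):
        # independent oracle: scikit-learn's PLSRegression on the same
        # centered data
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 8))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        y = (labels == "b").astype(float)
        s = pareto_scale(X)
        model = plsda_fit(s, labels, ncomp=3)

        sk = PLSRegression(n_components=3, scale=False).fit(s.values, y)
        Xres = s.values - sk.x_scores_ @ sk.x_loadings_.T
        r2x_sk = 1.0 - np.sum(Xres**2) / np.sum(s.values**2)
        yc = y - y.mean()
        yres = yc - sk.x_scores_ @ sk.y_loadings_.ravel()
        r2y_sk = 1.0 - np.sum(yres**2) / np.sum(yc**2)
        assert model.r2x_cum == pytest.approx(r2x_sk, abs=1e-6)
        assert model.r2y_cum == pytest.approx(r2y_sk, abs=1e-6)


class TestVIP:
    def test_equal_weights_give_unit_vip(self):
        y01 = np.array([0.0] * 4 + [1.0] * 4)
        X = np.column_stack([y01 + 0.0, y01 + 0.0, -y01 + 0.0, -y01 + 0.0])
        X = X + np.random.default_rng(7).normal(0, 1e-9, X.shape)
        model = plsda_fit(pareto_scale(X), ["a"] * 4 + ["b"] * 4, ncomp=1)
        assert np.allclose(model.vip, 1.0, atol=1e-3)

    def test_vip_normalization_identity(self):
        X, labels = _two_group_data(seed=8)
        model = plsda_fit(pareto_scale(X), labels, ncomp=3)
        assert np.sum(model.vip**2) == pytest.approx(X.shape[1], abs=1e-9)

    def test_hand_evaluated_two_feature_toy(self):
        # one component, w = (0.8, 0.6): VIP_j = sqrt(2 w_j^2)
        model = PLSDAModel(
            ncomp=1,
            weights=np.array([[0.8], [0.6]]),
            x_loadings=np.array([[0.8], [0.6]]),
            y_loadings=np.array([1.0]),
            scores=np.array([[1.0], [-1.0]]),
            vip=np.array([]),
            r2x_cum=1.0, r2y_cum=1.0, y_mean=0.5,
        )
        vip = vip_scores(model)
        assert vip == pytest.approx([1.1314, 0.8485], abs=1e-4)


class TestCrossValidation:
    def test_strong_separation_classified_accurately(self):
        X, labels = _two_group_data(n0=30, n1=20, delta=3.0, seed=9)
        q2, acc = cross_validate(pareto_scale(X), labels, ncomp=3, folds=5, seed=0)
        assert acc >= 0.9
        assert q2 > 0.5

    def test_same_seed_reproduces_folds_and_metrics(self):
        X, labels = _two_group_data(seed=10)
        a = cross_validate(pareto_scale(X), labels, ncomp=2, folds=4, seed=3)
        b = cross_validate(pareto_scale(X), labels, ncomp=2, folds=4, seed=3)
        assert a == b

    def test_infeasible_folds_raise_with_suggestion(self):
        X, labels = _two_group_data(n0=10, n1=4)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(pareto_scale(X), labels, folds=8)

    def test_randomized_labels_have_low_q2(self):
        rng = np.random.default_rng(11)
        hits = 0
        X, labels = _two_group_data(n0=25, n1=15, delta=2.0, seed=11)
        for k in range(25):
            perm = rng.permutation(labels)
            q2, _ = cross_validate(pareto_scale(X), perm, ncomp=3, folds=5,
                                   seed=k)
            hits += q2 <= 0.2
        assert hits >= 23  # >= 95% expected under the null

    def test_constant_feature_matrix_gives_p_one(self):
        X = np.ones((12, 4))
        labels = ["a"] * 6 + ["b"] * 6
        res = permutation_test(pareto_scale(X), labels, ncomp=2, n_perm=50, seed=0)
        assert res.p_value == 1.0


class TestPermutationTest:
    def test_strong_separation_reaches_the_minimum_p(self):
        X, labels = _two_group_data(n0=30, n1=20, delta=3.0, seed=12)
        res = permutation_test(pareto_scale(X), labels, ncomp=3, n_perm=200,
                               seed=1)
        assert res.p_value == pytest.approx(1.0 / 201.0)

    def test_seeded_determinism(self):
        X, labels = _two_group_data(seed=13)
        r1 = permutation_test(pareto_scale(X), labels, n_perm=50, seed=2)
        r2 = permutation_test(pareto_scale(X), labels, n_perm=50, seed=2)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.permuted_statistics, r2.permuted_statistics)

    def test_cv_accuracy_statistic_selectable(self):
        X, labels = _two_group_data(n0=16, n1=10, delta=3.0, seed=14)
        res = permutation_test(pareto_scale(X), labels, ncomp=2, n_perm=20,
                               statistic="cv-accuracy", seed=3)
        assert res.p_value <= 0.1
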