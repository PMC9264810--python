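"""PCA, Fisher LDA, NIPALS PLS-DA + VIP, and linear SVM against
independent oracles (dense SVD/eigendecompositions, closed forms,
scikit-learn reference fits)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sersdisc.chemometrics import (
    lda_fit,
    lda_predict,
    pca_fit,
    pca_project,
    plsda_decision,
    plsda_fit,
    plsda_predict,
    svm_fit_linear,
    vip_scores,
)
from sersdisc.exceptions import RankError
from sersdisc.types import CONTROL, PATIENT


def _labels(n_neg, n_pos):
    return np.array([CONTROL] * n_neg + [PATIENT] * n_pos, dtype=object)


class TestPCA:
    def test_collinear_points(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        model = pca_fit(X, 1)
        np.testing.assert_allclose(np.abs(model.loadings[:, 0]),
                                   [2**-0.5, 2**-0.5], atol=1e-12)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_rank_completeness(self, rng):
        X = rng.normal(size=(8, 5))
        model = pca_fit(X, 5)
        assert model.explained_variance_ratio.sum() == pytest.approx(
            1.0, abs=1e-9
        )

    def test_reconstruction_matches_svd_optimum(self, rng):
        """Truncated reconstruction error equals the dense-SVD optimum."""
        X = rng.normal(size=(10, 50))
        Xc = X - X.mean(axis=0)
        _, s, _ = np.linalg.svd(Xc, full_matrices=False)
        for k in (1, 3, 6):
            model = pca_fit(X, k)
            scores = pca_project(model, X)
            resid = Xc - scores @ model.loadings.T
            optimum = np.sqrt((s[k:] ** 2).sum())
            assert np.linalg.norm(resid) == pytest.approx(optimum, rel=1e-8)

    def test_ratios_match_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(20, 12))
        model = pca_fit(X, 8)
        cov = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            model.explained_variance_ratio, (eig / eig.sum())[:8], atol=1e-8
        )

    def test_orthonormal_loadings_and_sign_convention(self, rng):
        X = rng.normal(size=(15, 9))
        model = pca_fit(X, 4)
        V = model.loadings
        np.testing.assert_allclose(V.T @ V, np.eye(4), atol=1e-8)
        for k in range(4):
            j = np.argmax(np.abs(V[:, k]))
            assert V[j, k] > 0

    def test_projection_centering_identities(self, rng):
        X = rng.normal(size=(12, 6))
        model = pca_fit(X, 3)
        scores = pca_project(model, X)
        np.testing.assert_allclose(scores.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(
            pca_project(model, model.center[None, :]), 0, atol=1e-9
        )
        new = model.center + model.loadings[:, 0]
        np.testing.assert_allclose(
            pca_project(model, new[None, :])[0], [1, 0, 0], atol=1e-9
        )

    def test_rank_error(self):
        X = np.ones((4, 3)) + np.outer(np.arange(4.0), np.ones(3))
        with pytest.raises(RankError):
            pca_fit(X, 2)  # rank-1 centered matrix


class TestLDA:
    def test_symmetric_classes_axis_direction(self):
        X = np.array([
            [-2.0, 0.4], [-2.0, -0.4], [-1.0, 0.2], [-1.0, -0.2],
            [2.0, 0.4], [2.0, -0.4], [1.0, 0.2], [1.0, -0.2],
        ])
        model = lda_fit(X, _labels(4, 4))
        d = model.direction / np.linalg.norm(model.direction)
        assert abs(d[0]) > 0.999
        assert model.threshold == pytest.approx(0.0, abs=1e-9)

    def test_scale_equivariance(self, rng):
        X = rng.normal(size=(20, 2)) + np.r_[np.zeros((10, 2)),
                                             np.ones((10, 2))]
        lab = _labels(10, 10)
        m1 = lda_fit(X, lab)
        m5 = lda_fit(5.0 * X, lab)
        d1 = m1.direction / np.linalg.norm(m1.direction)
        d5 = m5.direction / np.linalg.norm(m5.direction)
        np.testing.assert_allclose(d5, d1, atol=1e-8)

    def test_direction_matches_fisher_closed_form(self):
        """n=200/200 Gaussians: fitted direction within 5° of Σ⁻¹Δμ."""
        rng = np.random.default_rng(42)
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        L = np.linalg.cholesky(cov)
        mu = np.array([1.5, -0.5])
        Xn = rng.normal(size=(200, 2)) @ L.T
        Xp = rng.normal(size=(200, 2)) @ L.T + mu
        model = lda_fit(np.vstack([Xn, Xp]), _labels(200, 200))
        oracle = np.linalg.solve(cov, mu)
        cosine = model.direction @ oracle / (
            np.linalg.norm(model.direction) * np.linalg.norm(oracle)
        )
        assert np.degrees(np.arccos(np.clip(cosine, -1, 1))) < 5.0

    def test_predict_means_and_tie_rule(self):
        X = np.array([[-1.0], [-2.0], [1.0], [2.0]])
        model = lda_fit(X, _labels(2, 2))
        assert lda_predict(model, np.array([[1.5]]))[0] == PATIENT
        assert lda_predict(model, np.array([[-1.5]]))[0] == CONTROL
        # exactly on the boundary with equal priors → negative class
        boundary = model.threshold / model.direction[0]
        assert lda_predict(model, np.array([[boundary]]))[0] == CONTROL

    def test_empirical_error_near_bayes_count(self):
        """Sampling the fitted two-Gaussian model reproduces its analytic
        Bayes error count within 3 of 200."""
        rng = np.random.default_rng(7)
        mu = np.array([2.4, 0.0])
        Xn = rng.normal(size=(150, 2))
        Xp = rng.normal(size=(150, 2)) + mu
        model = lda_fit(np.vstack([Xn, Xp]), _labels(150, 150))
        d = model.direction
        # the model's own projected Gaussians
        m_neg, m_pos = 0.0, mu @ d
        sigma = np.linalg.norm(d)  # identity covariance
        from scipy.stats import norm

        err_neg = norm.sf((model.threshold - m_neg) / sigma)
        err_pos = norm.cdf((model.threshold - m_pos) / sigma)
        bayes_count = 100 * err_neg + 100 * err_pos
        Sn = rng.normal(size=(100, 2))
        Sp = rng.normal(size=(100, 2)) + mu
        pred = lda_predict(model, np.vstack([Sn, Sp]))
        observed = int(np.sum(pred[:100] == PATIENT)) + int(
            np.sum(pred[100:] == CONTROL)
        )
        assert abs(observed - bayes_count) <= 3

    def test_1d_equal_priors_degenerates_to_midpoint(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        model = lda_fit(X, _labels(2, 2))
        assert model.threshold / model.direction[0] == pytest.approx(6.0)


class TestPLSDA:
    def test_rank1_exact_fit(self):
        y01 = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        X = (2.0 * y01 - 3.0)[:, None]
        lab = np.where(y01 == 1, PATIENT, CONTROL).astype(object)
        model = plsda_fit(X, lab, n_components=1)
        np.testing.assert_allclose(plsda_decision(model, X), y01, atol=1e-9)
        assert list(plsda_predict(model, X)) == list(lab)

    def test_first_weight_is_cross_covariance(self, rng):
        X = rng.normal(size=(15, 6))
        lab = _labels(7, 8)
        y = (lab == PATIENT).astype(float)
        model = plsda_fit(X, lab, n_components=2)
        Xc = X - X.mean(axis=0)
        w_oracle = Xc.T @ (y - y.mean())
        w_oracle /= np.linalg.norm(w_oracle)
        np.testing.assert_allclose(model.x_weights[:, 0], w_oracle, atol=1e-10)

    @pytest.mark.parametrize("shape", [(12, 8), (20, 100)])
    def test_regression_vector_matches_sklearn(self, shape):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        X = rng.normal(size=shape)
        lab = _labels(shape[0] // 2, shape[0] - shape[0] // 2)
        model = plsda_fit(X, lab, n_components=2)
        sk = PLSRegression(n_components=2, scale=False).fit(
            X, (lab == PATIENT).astype(float)
        )
        np.testing.assert_allclose(model.coef, sk.coef_.ravel(), atol=1e-6)

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(12, 5))
        lab = _labels(6, 6)
        y = (lab == PATIENT).astype(float)
        model = plsda_fit(X, lab, n_components=5)
        Xc = np.column_stack([np.ones(12), X])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        ols_pred = Xc @ beta
        np.testing.assert_allclose(
            plsda_decision(model, X), ols_pred, atol=1e-6
        )

    def test_column_mean_predicts_class_rate(self, rng):
        X = rng.normal(size=(10, 4))
        lab = _labels(4, 6)
        model = plsda_fit(X, lab, n_components=2)
        yhat = plsda_decision(model, X.mean(axis=0)[None, :])[0]
        assert yhat == pytest.approx(0.6, abs=1e-9)
        assert plsda_predict(model, X.mean(axis=0)[None, :])[0] == PATIENT


class TestVIP:
    def test_uniform_weights_give_unit_vip(self):
        y01 = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        X = np.tile((y01 - y01.mean())[:, None], (1, 7))
        lab = np.where(y01 == 1, PATIENT, CONTROL).astype(object)
        model = plsda_fit(X, lab, n_components=1)
        vip = vip_scores(model)
        np.testing.assert_allclose(vip.vip, 1.0, atol=1e-10)

    def test_concentrated_weight(self):
        y01 = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        X = np.zeros((6, 5))
        X[:, 2] = y01 - y01.mean()
        lab = np.where(y01 == 1, PATIENT, CONTROL).astype(object)
        vip = vip_scores(plsda_fit(X, lab, n_components=1))
        assert vip.vip[2] == pytest.approx(np.sqrt(5.0), abs=1e-9)
        np.testing.assert_allclose(np.delete(vip.vip, 2), 0.0, atol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 3))
    def test_normalization_invariant(self, seed, k):
        """Σ VIP² = p for every fitted model."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(14, 9))
        lab = _labels(6, 8)
        vip = vip_scores(plsda_fit(X, lab, n_components=k))
        assert (vip.vip**2).sum() == pytest.approx(9.0, abs=1e-8)


class TestSVM:
    def test_four_point_max_margin_oracle(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [2.0, 0.0], [2.0, 1.0]])
        model = svm_fit_linear(X, _labels(2, 2), cost=100.0)
        # hand solution: w = (1, 0), b = −1 → threshold 1
        np.testing.assert_allclose(model.direction, [1.0, 0.0], atol=1e-3)
        assert model.threshold == pytest.approx(1.0, abs=1e-3)

    def test_label_flip_negates_rule(self, rng):
        X = rng.normal(size=(20, 2)) + np.r_[np.zeros((10, 2)),
                                             np.full((10, 2), 1.2)]
        m = svm_fit_linear(X, _labels(10, 10))
        flipped = np.array([PATIENT] * 10 + [CONTROL] * 10, dtype=object)
        mf = svm_fit_linear(X, flipped)
        np.testing.assert_allclose(mf.direction, -m.direction, atol=1e-6)
        assert mf.threshold == pytest.approx(-m.threshold, abs=1e-6)

    def test_separable_large_cost_zero_errors(self, rng):
        X = np.r_[rng.normal(size=(12, 2)), rng.normal(size=(12, 2)) + 5.0]
        lab = _labels(12, 12)
        model = svm_fit_linear(X, lab, cost=1000.0)
        assert np.all(lda_predict(model, X) == lab)

    def test_agreement_with_sklearn(self, rng):
        from sklearn.svm import SVC

        X = rng.normal(size=(40, 2))
        X[:18] += [1.4, 0.6]
        lab = np.array([PATIENT] * 18 + [CONTROL] * 22, dtype=object)
        model = svm_fit_linear(X, lab, cost=1.0)
        sk = SVC(kernel="linear", C=1.0, tol=1e-6).fit(
            X, (lab == PATIENT).astype(int)
        )
        np.testing.assert_allclose(model.direction, sk.coef_[0], atol=1e-3)
        assert -model.threshold == pytest.approx(sk.intercept_[0], abs=1e-3)
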