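import numpy as np
import pytest
from scipy import linalg

from ftirdx.errors import SingularityError
from ftirdx.qda import (CappedVariancePCA, ShrinkageQDA, fit_pca, fit_qda,
                        make_pca_qda, project, qda_score)


def gaussian_density_scores(model, X):
    """Oracle: Q_ik = -2 log(pi_k phi_k(x)) - d log(2 pi), with phi_k the
    multivariate normal density, computed independently via slogdet/inv."""
    X = np.atleast_2d(X)
    d = X.shape[1]
    out = np.empty((X.shape[0], model.classes_.size))
    for k in range(model.classes_.size):
        S = model.covariances_[k]
        sign, logdet = np.linalg.slogdet(S)
        assert sign > 0
        Sinv = np.linalg.inv(S)
        for i, x in enumerate(X):
            diff = x - model.means_[k]
            logphi = -0.5 * (d * np.log(2 * np.pi) + logdet + diff @ Sinv @ diff)
            out[i, k] = -2.0 * (np.log(model.priors_[k]) + logphi) \
                - d * np.log(2 * np.pi)
    return out


@pytest.fixture
def one_d_model():
    """Two 1-D classes with means 0 and 3, unit sample variance each."""
    X = np.array([[-1.0], [0.0], [1.0], [2.0], [3.0], [4.0]])
    y = np.array(["a", "a", "a", "b", "b", "b"])
    return fit_qda(X, y, priors="uniform", shrinkage=0.0), X, y


class TestPCA:
    def test_planar_data_needs_two_components(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 10))
        X = rng.normal(size=(40, 2)) @ basis + rng.normal(size=10)
        p = fit_pca(X, variance_target=0.99, max_components=None)
        assert p.n_components_ == 2
        assert np.isclose(p.explained_variance_ratio_.sum(), 1.0)

    def test_explained_variance_matches_brute_force_eigensolve(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(3, 3))
        p = fit_pca(X, n_components=2, max_components=None)
        C = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.allclose(p.explained_variance_, eig[:2], atol=1e-10)

    def test_loadings_orthonormal_and_ratios_monotone(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 8))
        p = fit_pca(X, n_components=5, max_components=None)
        assert np.allclose(p.loadings_.T @ p.loadings_, np.eye(5), atol=1e-10)
        assert np.all(np.diff(p.explained_variance_ratio_) <= 1e-12)

    def test_projection_contract(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 5))
        p = fit_pca(X, n_components=5, max_components=None)
        # the training mean projects to the origin
        assert np.allclose(project(p, p.mean_[None, :]), 0.0, atol=1e-10)
        # full-rank reconstruction
        S = project(p, X)
        assert np.allclose(S @ p.loadings_.T + p.mean_, X, atol=1e-9)
        # scores equal the brute-force centred product
        assert np.allclose(S, (X - X.mean(axis=0)) @ p.loadings_, atol=1e-9)

    def test_rank_deficient_request_rejected(self):
        X = np.zeros((4, 6))
        X[:, 0] = [0, 1, 2, 3]
        with pytest.raises(ValueError):
            fit_pca(X, n_components=5, max_components=None)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 6))
        p1 = fit_pca(X, n_components=3)
        p2 = fit_pca(X[::-1].copy(), n_components=3)
        for r in range(3):
            j = np.argmax(np.abs(p1.loadings_[:, r]))
            assert p1.loadings_[j, r] > 0
        assert np.allclose(np.abs(p1.loadings_), np.abs(p2.loadings_), atol=1e-8)


class TestQDAFit:
    def test_hand_computed_two_class_model(self, one_d_model):
        m, _, _ = one_d_model
        assert np.allclose(m.means_.ravel(), [0.0, 3.0])
        assert np.allclose(m.covariances_.ravel(), [1.0, 1.0])
        assert np.allclose(m.priors_, [0.5, 0.5])

    def test_full_shrinkage_gives_pooled_covariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        y = np.repeat(["a", "b", "c"], 10)
        m = fit_qda(X, y, shrinkage=1.0)
        assert np.allclose(m.covariances_[0], m.covariances_[1])
        assert np.allclose(m.covariances_[0], m.covariances_[2])

    def test_small_class_with_shrinkage_is_positive_definite(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(24, 6))
        y = np.array(["lgd"] * 4 + ["oac"] * 20)
        m = fit_qda(X, y, shrinkage=0.5)
        for S in m.covariances_:
            assert np.linalg.eigvalsh(S).min() > 0

    def test_singleton_class_without_shrinkage_raises(self):
        X = np.arange(6, dtype=float).reshape(3, 2)
        y = np.array(["a", "a", "b"])
        with pytest.raises(SingularityError, match="shrinkage"):
            fit_qda(X, y, shrinkage=0.0)


class TestQDAScore:
    def test_zero_at_class_mean_identity_covariance(self):
        # single-class model: prior 1 and identity covariance give Q = 0
        X = np.array([[1.0, -1.0], [-1.0, 1.0], [1.0, 1.0], [-1.0, -1.0]])
        y = np.array(["a"] * 4)
        m = ShrinkageQDA(shrinkage=0.0).fit(X, y)
        m.covariances_[0] = np.eye(2)
        m._chols = [np.eye(2)]
        m.log_dets_ = np.array([0.0])
        assert np.allclose(qda_score(m, m.means_[0]), 0.0, atol=1e-12)

    def test_hand_arithmetic_and_tie_at_midpoint(self, one_d_model):
        m, _, _ = one_d_model
        q = qda_score(m, np.array([1.5]))
        expected = 1.5**2 - 2 * np.log(0.5)
        assert np.allclose(q, [expected, expected], atol=1e-12)
        assert np.isclose(expected, 3.6362943611, atol=1e-9)

    def test_agrees_with_gaussian_density_oracle(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(loc, 1.0, size=(30, 4))
                       for loc in (0.0, 2.0, -2.0)])
        y = np.repeat(["a", "b", "c"], 30)
        m = fit_qda(X, y, shrinkage=0.3)
        pts = rng.normal(size=(200, 4))
        assert np.allclose(m.qda_scores(pts), gaussian_density_scores(m, pts),
                           atol=1e-9)


class TestPredict:
    def test_one_d_assignments_and_tie_break(self, one_d_model):
        m, _, _ = one_d_model
        assert m.predict(np.array([[-1.0], [4.0]])).tolist() == ["a", "b"]
        # exact tie at the midpoint: first class in order wins (equal priors)
        assert m.predict(np.array([[1.5]]))[0] == "a"

    def test_tie_break_prefers_larger_prior(self):
        X = np.array([[-1.0], [0.0], [1.0], [2.0], [3.0], [4.0]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        m = ShrinkageQDA(priors=[0.3, 0.7], shrinkage=1.0).fit(X, y)
        # force an exact score tie: the declared policy picks the larger prior
        m.qda_scores = lambda Z: np.zeros((np.atleast_2d(Z).shape[0], 2))
        assert m.predict(np.array([[1.5]]))[0] == "b"

    def test_matches_posterior_argmax_oracle(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(c, s, size=(40, 3))
                       for c, s in ((0, 1.0), (3, 2.0), (-3, 0.5))])
        y = np.repeat(["u", "v", "w"], 40)
        m = fit_qda(X, y, shrinkage=0.2)
        pts = rng.normal(scale=3.0, size=(200, 3))
        pred = m.predict(pts)
        oracle = m.classes_[np.argmin(gaussian_density_scores(m, pts), axis=1)]
        assert np.array_equal(pred, oracle)


class TestInvariances:
    def test_prediction_invariant_under_invertible_linear_maps(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(c, 1.0, size=(25, 4)) for c in (0, 3, -3)])
        y = np.repeat(["a", "b", "c"], 25)
        pts = rng.normal(scale=2.0, size=(50, 4))
        base = fit_qda(X, y, shrinkage=0.0).predict(pts)
        for _ in range(5):
            A = rng.normal(size=(4, 4))
            A += 4.0 * np.eye(4)  # keep it well-conditioned
            mapped = fit_qda(X @ A, y, shrinkage=0.0).predict(pts @ A)
            assert np.array_equal(mapped, base)

    def test_equal_covariances_reduce_to_nearest_mahalanobis_mean(self):
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(c, 1.0, size=(30, 3)) for c in (0, 4)])
        y = np.repeat(["a", "b"], 30)
        m = fit_qda(X, y, priors="uniform", shrinkage=1.0)
        pts = rng.normal(scale=3.0, size=(80, 3))
        S = m.covariances_[0]
        Sinv = np.linalg.inv(S)
        d2 = np.stack([np.einsum("ij,jk,ik->i", pts - mu, Sinv, pts - mu)
                       for mu in m.means_], axis=1)
        assert np.array_equal(m.predict(pts), m.classes_[np.argmin(d2, axis=1)])

    def test_pca_qda_end_to_end_matches_density_oracle(self, specimens_default):
        sp, _ = specimens_default
        pipe = make_pca_qda().fit(sp.absorbance, sp.class_label)
        scores = pipe.named_steps["pca"].transform(sp.absorbance)
        qda = pipe.named_steps["qda"]
        oracle = qda.classes_[np.argmin(gaussian_density_scores(qda, scores),
                                        axis=1)]
        assert np.array_equal(pipe.predict(sp.absorbance), oracle)
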