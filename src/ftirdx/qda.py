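"""Quadratic discriminant analysis with shrinkage, and its PCA front-end.

The discriminant score for sample :math:`x_i` against class :math:`k` is

.. math::

    Q_{ik} = (x_i - \\bar{x}_k)^T \\Sigma_k^{-1} (x_i - \\bar{x}_k)
             + \\log_e |\\Sigma_k| - 2 \\log_e \\pi_k,

a squared Mahalanobis distance penalised by the log covariance volume and
the class prior; samples are assigned to the class with the **minimum**
score (equivalently the maximum Gaussian posterior).  Unlike linear
discriminant analysis each class keeps its own variance-covariance matrix
:math:`\\Sigma_k`.

Tissue studies fit this model with very small classes (down to n = 4
specimens) on several variables, where the raw class covariance is
singular.  :class:`ShrinkageQDA` therefore shrinks each class covariance
toward the pooled within-class covariance with weight ``shrinkage``
(:math:`\\lambda \\in [0, 1]`; 0 = pure QDA, 1 = shared covariance, i.e.
LDA-like), with a small trace-scaled ridge as a fallback when even the
shrunk matrix is not positive definite.

:class:`CappedVariancePCA` is the scores front-end for PCA-QDA: a
mean-centred PCA keeping the smallest number of components reaching a
cumulative explained-variance target, capped at a maximum count, with the
component sign convention that the largest-magnitude loading entry is
positive (making the decomposition deterministic).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.pipeline import Pipeline
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import ConfigError, SingularityError

_RIDGE_FACTOR = 1e-8  # ridge added as factor * trace/d when PD check fails


def _chol_with_ridge(S: np.ndarray):
    """Cholesky of S, adding a trace-scaled ridge if S is not PD.

    Returns (lower_triangular_factor, possibly-ridged S).
    """
    d = S.shape[0]
    try:
        return linalg.cholesky(S, lower=True), S
    except linalg.LinAlgError:
        ridge = _RIDGE_FACTOR * np.trace(S) / d
        if ridge <= 0:
            ridge = _RIDGE_FACTOR
        S2 = S + ridge * np.eye(d)
        return linalg.cholesky(S2, lower=True), S2


class ShrinkageQDA(ClassifierMixin, BaseEstimator):
    """Quadratic discriminant analysis classifying by minimum penalised score.

    Parameters
    ----------
    priors : {"empirical", "uniform"} or array of shape (n_classes,)
        Class prior probabilities pi_k.  "empirical" uses training class
        frequencies.
    shrinkage : float in [0, 1]
        Weight lambda pulling each class covariance toward the pooled
        within-class covariance: Sigma_k <- (1-lambda) Sigma_k + lambda
        Sigma_pooled.

    Attributes
    ----------
    classes_ : ordered class labels.
    means_ : (n_classes, d) class mean vectors.
    covariances_ : (n_classes, d, d) regularised class covariances.
    log_dets_ : (n_classes,) log determinants of the stored covariances.
    priors_ : (n_classes,) priors, positive, summing to 1.
    """

    def __init__(self, priors="empirical", shrinkage: float = 0.5):
        self.priors = priors
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y, dtype=object))
        lam = float(self.shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ConfigError(f"shrinkage must be in [0, 1], got {lam}")
        classes, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        counts = np.bincount(y_idx, minlength=classes.size)
        if np.any(counts < 2) and lam == 0.0:
            small = classes[counts < 2]
            raise SingularityError(
                f"classes {list(small)} have < 2 samples; the raw class "
                "covariance is undefined — use shrinkage > 0"
            )
        if np.any(counts < 1):
            raise ValueError("every class needs at least one sample")

        means = np.vstack([X[y_idx == k].mean(axis=0) for k in range(classes.size)])
        raw = []
        pooled = np.zeros((d, d))
        for k in range(classes.size):
            Xi = X[y_idx == k] - means[k]
            # sample covariance, denominator n_k - 1 (zero matrix for n_k = 1)
            Sk = (Xi.T @ Xi) / max(counts[k] - 1, 1)
            raw.append(Sk)
            pooled += Xi.T @ Xi
        pooled /= max(n - classes.size, 1)

        covs, chols, log_dets = [], [], []
        for k in range(classes.size):
            Sk = (1.0 - lam) * raw[k] + lam * pooled
            Sk = (Sk + Sk.T) / 2.0
            L, Sk = _chol_with_ridge(Sk)
            covs.append(Sk)
            chols.append(L)
            log_dets.append(2.0 * np.sum(np.log(np.diag(L))))

        if isinstance(self.priors, str):
            if self.priors == "empirical":
                priors = counts / n
            elif self.priors == "uniform":
                priors = np.full(classes.size, 1.0 / classes.size)
            else:
                raise ConfigError(f"unknown priors mode {self.priors!r}")
        else:
            priors = np.asarray(self.priors, dtype=float)
            if priors.size != classes.size or np.any(priors <= 0):
                raise ConfigError("priors must be positive, one per class")
            priors = priors / priors.sum()

        self.classes_ = classes
        self.means_ = means
        self.covariances_ = np.stack(covs)
        self._chols = chols
        self.log_dets_ = np.asarray(log_dets)
        self.priors_ = priors
        self.n_features_in_ = d
        return self

    def qda_scores(self, X) -> np.ndarray:
        """Per-class penalised scores Q_ik (n_samples, n_classes); lower wins."""
        check_is_fitted(self, "classes_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with "
                f"{self.n_features_in_}"
            )
        Q = np.empty((X.shape[0], self.classes_.size))
        for k, L in enumerate(self._chols):
            Z = linalg.solve_triangular(L, (X - self.means_[k]).T, lower=True)
            maha = np.sum(Z * Z, axis=0)
            Q[:, k] = maha + self.log_dets_[k] - 2.0 * np.log(self.priors_[k])
        return Q

    def decision_function(self, X) -> np.ndarray:
        """Negated scores, so that larger means more likely (sklearn sense)."""
        return -self.qda_scores(X)

    def predict(self, X) -> np.ndarray:
        """Assign each sample the class of minimum score.

        Exact ties are broken by the larger prior, then by class order.
        """
        Q = self.qda_scores(X)
        # lexicographic tie-break: score, then -prior, then class position
        order = np.lexsort(
            (
                np.broadcast_to(np.arange(self.classes_.size), Q.shape),
                np.broadcast_to(-self.priors_, Q.shape),
                Q,
            ),
            axis=1,
        )
        return self.classes_[order[:, 0]]


class CappedVariancePCA(TransformerMixin, BaseEstimator):
    """Mean-centred PCA keeping components up to a variance target and cap.

    Parameters
    ----------
    variance_target : float in (0, 1]
        Keep the smallest number of components whose cumulative explained
        variance reaches this fraction.
    max_components : int or None
        Upper bound on the number of components kept (applied after the
        variance target); None means no cap.
    n_components : int or None
        If given, overrides the variance-target rule entirely.

    Attributes
    ----------
    n_components_, mean_, loadings_ (d x m, orthonormal columns),
    explained_variance_ratio_.
    """

    def __init__(self, variance_target: float = 0.935, max_components: int | None = 6,
                 n_components: int | None = None):
        self.variance_target = variance_target
        self.max_components = max_components
        self.n_components = n_components

    def fit(self, X, y=None):
        X = check_array(X)
        n, d = X.shape
        max_rank = min(n - 1, d)
        if max_rank < 1:
            raise ValueError("PCA needs at least 2 samples")
        pca = PCA(n_components=max_rank, svd_solver="full")
        pca.fit(X)
        if self.n_components is not None:
            m = int(self.n_components)
            if m < 1 or m > max_rank:
                raise ValueError(
                    f"n_components={m} outside [1, {max_rank}] for this data"
                )
        else:
            cum = np.cumsum(pca.explained_variance_ratio_)
            m = int(np.searchsorted(cum, self.variance_target - 1e-12) + 1)
            m = min(m, max_rank)
            if self.max_components is not None:
                m = min(m, int(self.max_components))
        components = pca.components_[:m].copy()
        # deterministic sign: largest-|.| entry of each loading made positive
        for r in range(m):
            j = int(np.argmax(np.abs(components[r])))
            if components[r, j] < 0:
                components[r] *= -1.0
        self.mean_ = pca.mean_
        self.loadings_ = components.T
        self.explained_variance_ = pca.explained_variance_[:m].copy()
        self.explained_variance_ratio_ = pca.explained_variance_ratio_[:m].copy()
        self.n_components_ = m
        self.n_features_in_ = d
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return (X - self.mean_) @ self.loadings_


# --- functional wrappers --------------------------------------------------

def fit_pca(X, n_components=None, variance_target: float = 0.935,
            max_components: int | None = 6) -> CappedVariancePCA:
    """Fit the PCA front-end; integer ``n_components`` overrides the target."""
    return CappedVariancePCA(
        variance_target=variance_target,
        max_components=max_components,
        n_components=n_components,
    ).fit(X)


def project(p: CappedVariancePCA, X) -> np.ndarray:
    """Scores = (X - mean) @ loadings."""
    return p.transform(X)


def fit_qda(X, y, priors="empirical", shrinkage: float = 0.5) -> ShrinkageQDA:
    return ShrinkageQDA(priors=priors, shrinkage=shrinkage).fit(X, y)


def qda_score(model: ShrinkageQDA, x) -> np.ndarray:
    """Scores Q_ik for a single feature vector (1-D) or matrix of vectors."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return model.qda_scores(x[None, :])[0]
    return model.qda_scores(x)


def predict(model: ShrinkageQDA, X):
    """Labels plus the per-class score matrix, for audit."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return model.predict(X), model.qda_scores(X)


def make_pca_qda(variance_target: float = 0.935, max_components: int | None = 6,
                 n_components: int | None = 6, priors="empirical",
                 shrinkage: float = 0.5) -> Pipeline:
    """PCA-QDA as an sklearn Pipeline (scores front-end + ShrinkageQDA).

    The default keeps the scores on six principal components — the
    standard operating point for this kind of tissue study; pass
    ``n_components=None`` to fall back to the cumulative variance-target
    rule of :class:`CappedVariancePCA`.
    """
    return Pipeline(
        [
            ("pca", CappedVariancePCA(variance_target=variance_target,
                                      max_components=max_components,
                                      n_components=n_components)),
            ("qda", ShrinkageQDA(priors=priors, shrinkage=shrinkage)),
        ]
    )
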