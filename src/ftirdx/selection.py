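"""Wavenumber selection driven by the average misclassification risk G.

For a validation spectrum :math:`x_n` of class :math:`I(n)`, the risk ratio

.. math::

    g_n = \\frac{r^2(x_n, m_{I(n)})}
               {\\min_{I(m) \\neq I(n)} r^2(x_n, m_{I(m)})}

compares the squared Mahalanobis distance to the spectrum's own class mean
with the distance to the centre of the nearest *wrong* class, and

.. math::  G = \\frac{1}{N_V} \\sum_{n=1}^{N_V} g_n

averages it over the :math:`N_V` validation spectra.  G is small when the
candidate variables place every validation spectrum close to its own class
and far from the others, so *minimising G* drives the two wrapper
selectors:

* **SPA** (successive projections algorithm) — builds candidate chains of
  variables with maximal projections onto the orthogonal complement of the
  variables already chosen, then scores every chain prefix with G;
* **GA** — a genetic algorithm over binary inclusion masks of wavenumbers
  (tournament selection, single-point crossover, bit-flip mutation, one
  elite), restarted from independent random populations.

Both are also packaged as scikit-learn selector transformers
(:class:`SPASelector`, :class:`GASelector`) that carve an internal
stratified hold-out split from the training data to evaluate G, so they can
sit inside a Pipeline in front of a classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigError, SingularityError

_RIDGE_FACTOR = 1e-8


def mahalanobis_sq(x, centre, S) -> float:
    """Squared Mahalanobis distance (x - centre)^T S^{-1} (x - centre)."""
    x = np.asarray(x, dtype=float)
    centre = np.asarray(centre, dtype=float)
    S = np.atleast_2d(np.asarray(S, dtype=float))
    try:
        L = linalg.cholesky(S, lower=True)
    except linalg.LinAlgError as e:
        raise SingularityError(
            "covariance is singular on the selected variables; use the "
            "pooled or a regularised covariance"
        ) from e
    z = linalg.solve_triangular(L, x - centre, lower=True)
    return float(z @ z)


@dataclass
class RiskEvaluation:
    """Per-spectrum risk ratios g_n and their mean G over NV spectra."""

    gn: np.ndarray
    NV: int
    G: float
    infinite: int = 0  # spectra exactly at a wrong-class centre


def _class_means(X: np.ndarray, y_idx: np.ndarray, K: int) -> np.ndarray:
    return np.vstack([X[y_idx == k].mean(axis=0) for k in range(K)])


def _pooled_cov(X: np.ndarray, y_idx: np.ndarray, means: np.ndarray, K: int) -> np.ndarray:
    d = X.shape[1]
    S = np.zeros((d, d))
    for k in range(K):
        Xi = X[y_idx == k] - means[k]
        S += Xi.T @ Xi
    return S / max(X.shape[0] - K, 1)


def _chol_ridged(S: np.ndarray) -> np.ndarray:
    S = (S + S.T) / 2.0
    try:
        return linalg.cholesky(S, lower=True)
    except linalg.LinAlgError:
        ridge = _RIDGE_FACTOR * np.trace(S) / S.shape[0]
        if ridge <= 0:
            ridge = _RIDGE_FACTOR
        return linalg.cholesky(S + ridge * np.eye(S.shape[0]), lower=True)


class RiskEvaluator:
    """Reusable evaluator of the risk cost G for many variable subsets.

    Precomputes the class partition of a fixed train/validation pair so
    that wrapper searches (SPA chains, GA populations) can score thousands
    of candidate subsets cheaply via :meth:`evaluate`.
    """

    def __init__(self, X_train, y_train, X_valid, y_valid,
                 covariance_mode: str = "pooled", shrinkage: float = 0.5):
        self.X_train = np.ascontiguousarray(X_train, dtype=float)
        self.X_valid = np.ascontiguousarray(X_valid, dtype=float)
        if self.X_valid.shape[0] == 0:
            raise ValueError("validation set is empty")
        y_train = np.asarray(y_train)
        y_valid = np.asarray(y_valid)
        classes, self.y_idx = np.unique(y_train, return_inverse=True)
        self.K = classes.size
        if self.K < 2:
            raise ValueError("risk G needs at least two classes")
        counts = np.bincount(self.y_idx, minlength=self.K)
        if np.any(counts < 2):
            raise ValueError("each training class needs >= 2 samples")
        self.counts = counts
        lookup = {c: k for k, c in enumerate(classes)}
        try:
            self.yv_idx = np.array([lookup[c] for c in y_valid])
        except KeyError as e:
            raise ValueError(f"validation class {e} absent from training") from e
        if covariance_mode not in ("pooled", "per-class"):
            raise ConfigError(f"unknown covariance_mode {covariance_mode!r}")
        self.covariance_mode = covariance_mode
        self.shrinkage = shrinkage
        self.class_rows = [np.flatnonzero(self.y_idx == k) for k in range(self.K)]
        self._ar = np.arange(self.X_valid.shape[0])

    def evaluate(self, variables) -> RiskEvaluation:
        variables = np.asarray(variables, dtype=int)
        if variables.size == 0:
            raise ValueError("variables must be non-empty")
        Xt = self.X_train[:, variables]
        Xv = self.X_valid[:, variables]
        K = self.K
        means = np.empty((K, Xt.shape[1]))
        pooled = np.zeros((Xt.shape[1], Xt.shape[1]))
        centred = []
        for k in range(K):
            rows = Xt[self.class_rows[k]]
            means[k] = rows.mean(axis=0)
            Xi = rows - means[k]
            centred.append(Xi)
            pooled += Xi.T @ Xi
        pooled /= max(Xt.shape[0] - K, 1)
        r2 = np.empty((Xv.shape[0], K))
        if self.covariance_mode == "pooled":
            L = _chol_ridged(pooled)
            for k in range(K):
                Z = linalg.solve_triangular(L, (Xv - means[k]).T, lower=True)
                r2[:, k] = np.einsum("ij,ij->j", Z, Z)
        else:
            for k in range(K):
                Xi = centred[k]
                Sk = (Xi.T @ Xi) / max(self.counts[k] - 1, 1)
                Sk = (1.0 - self.shrinkage) * Sk + self.shrinkage * pooled
                L = _chol_ridged(Sk)
                Z = linalg.solve_triangular(L, (Xv - means[k]).T, lower=True)
                r2[:, k] = np.einsum("ij,ij->j", Z, Z)
        own = r2[self._ar, self.yv_idx]
        r2[self._ar, self.yv_idx] = np.inf
        nearest_wrong = r2.min(axis=1)
        # a validation spectrum exactly at a wrong-class centre carries
        # infinite risk (flagged), even if it also sits at its own centre
        with np.errstate(divide="ignore", invalid="ignore"):
            gn = np.where(nearest_wrong > 0, own / nearest_wrong, np.inf)
        infinite = int(np.sum(~np.isfinite(gn)))
        G = float(np.mean(gn)) if infinite == 0 else float("inf")
        return RiskEvaluation(gn=gn, NV=int(gn.size), G=G, infinite=infinite)


def risk_G(
    X_train,
    y_train,
    X_valid,
    y_valid,
    variables,
    covariance_mode: str = "pooled",
    shrinkage: float = 0.5,
) -> RiskEvaluation:
    """Average misclassification risk G of a candidate variable subset.

    Class means (and covariances) come from the training set only; G is the
    mean of the risk ratios g_n over the validation spectra.  Smaller is
    better.

    Parameters
    ----------
    covariance_mode : "pooled" (one within-class covariance for all
        distances; robust for tiny classes) or "per-class" (class-specific
        covariances, shrunk toward the pooled one with weight ``shrinkage``).
    """
    ev = RiskEvaluator(X_train, y_train, X_valid, y_valid,
                       covariance_mode=covariance_mode, shrinkage=shrinkage)
    return ev.evaluate(variables)


# --- successive projections algorithm ------------------------------------

@dataclass
class SPAResult:
    """Selected variable chain, its G, and the winning start's G curve."""

    indices: np.ndarray            # ordered as chained
    G: float
    g_curve: np.ndarray            # G versus chain length 1..max_vars
    start: int = 0


def _spa_chain(X: np.ndarray, start: int, max_vars: int) -> np.ndarray:
    """One successive-projections chain of column indices from ``start``.

    At each step the remaining column with the largest norm after projection
    onto the orthogonal complement of the chosen columns is appended.
    """
    n, p = X.shape
    R = X.copy()
    chain = [start]
    chosen = np.zeros(p, dtype=bool)
    chosen[start] = True
    for _ in range(max_vars - 1):
        v = R[:, chain[-1]]
        nv = np.linalg.norm(v)
        if nv <= 1e-12:
            break
        q = v / nv
        R = R - np.outer(q, q @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[chosen] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-12:
            break
        chain.append(nxt)
        chosen[nxt] = True
    return np.asarray(chain, dtype=int)


def spa_select(
    X_train,
    y_train,
    X_valid,
    y_valid,
    max_vars: int,
    covariance_mode: str = "pooled",
    starts=None,
) -> SPAResult:
    """Successive-projections selection scored by G over all chain prefixes.

    Every start wavenumber (all columns by default) seeds a chain; G is
    evaluated for each prefix length 1..max_vars and the (start, length)
    pair with minimum G wins.  Deterministic given its inputs.
    """
    X_train = np.asarray(X_train, dtype=float)
    p = X_train.shape[1]
    if not 1 <= max_vars <= p:
        raise ValueError(f"max_vars must be in [1, {p}]")
    if starts is None:
        starts = range(p)
    evaluator = RiskEvaluator(X_train, y_train, X_valid, y_valid,
                              covariance_mode=covariance_mode)
    best = None
    for s in starts:
        chain = _spa_chain(X_train, int(s), max_vars)
        curve = np.full(max_vars, np.nan)
        for m in range(1, chain.size + 1):
            g = evaluator.evaluate(chain[:m]).G
            curve[m - 1] = g
            if best is None or g < best.G:
                best = SPAResult(indices=chain[:m].copy(), G=g,
                                 g_curve=curve, start=int(s))
        if best is not None and best.start == int(s):
            best.g_curve = curve  # complete curve for the winning start
    return best


# --- genetic algorithm ----------------------------------------------------

@dataclass
class GAConfig:
    """Genetic-algorithm settings (defaults are the standard operating point:
    100 generations of 200 chromosomes, 60% crossover, 1% mutation, three
    independent restarts)."""

    generations: int = 100
    population: int = 200
    crossover_prob: float = 0.60
    mutation_prob: float = 0.01
    restarts: int = 3
    min_vars: int = 1
    max_vars: int | None = None

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ConfigError("population must be >= 2")
        if min(self.generations, self.restarts) < 1:
            raise ConfigError("generations and restarts must be >= 1")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.min_vars < 1:
            raise ConfigError("min_vars must be >= 1")
        if self.max_vars is not None and self.max_vars < self.min_vars:
            raise ConfigError("max_vars must be >= min_vars")


@dataclass
class GAResult:
    indices: np.ndarray
    G: float
    history: np.ndarray       # (restarts, generations) best G so far
    winner: int               # restart index of the returned solution


def _repair(bits: np.ndarray, cfg: GAConfig, rng: np.random.Generator) -> None:
    """Random bit flips until the selected count is inside [min, max]."""
    p = bits.size
    hi = cfg.max_vars if cfg.max_vars is not None else p
    k = int(bits.sum())
    while k < cfg.min_vars:
        off = np.flatnonzero(~bits)
        bits[rng.choice(off)] = True
        k += 1
    while k > hi:
        on = np.flatnonzero(bits)
        bits[rng.choice(on)] = False
        k -= 1


def ga_select(
    X_train,
    y_train,
    X_valid,
    y_valid,
    cfg: GAConfig | None = None,
    covariance_mode: str = "pooled",
    seed=0,
) -> GAResult:
    """Genetic-algorithm wavenumber selection minimising G.

    Binary chromosomes over the wavenumber axis; fitness is -G.  Tournament
    selection of size 2, single-point crossover, per-bit mutation, elitism
    of one, ``cfg.restarts`` independent populations; the lowest-G solution
    across restarts is returned.  Fully reproducible from ``seed``.
    """
    cfg = cfg or GAConfig()
    X_train = np.asarray(X_train, dtype=float)
    p = X_train.shape[1]
    rng = np.random.default_rng(seed)
    evaluator = RiskEvaluator(X_train, y_train, X_valid, y_valid,
                              covariance_mode=covariance_mode)
    cache: dict[bytes, float] = {}

    def fitness(bits: np.ndarray) -> float:
        key = bits.tobytes()
        g = cache.get(key)
        if g is None:
            g = evaluator.evaluate(np.flatnonzero(bits)).G
            cache[key] = g
        return g

    history = np.empty((cfg.restarts, cfg.generations))
    best_bits, best_g, winner = None, np.inf, -1
    for r in range(cfg.restarts):
        pop = rng.random((cfg.population, p)) < 0.5
        for bits in pop:
            _repair(bits, cfg, rng)
        scores = np.array([fitness(b) for b in pop])
        for gen in range(cfg.generations):
            elite = int(np.argmin(scores))
            new = [pop[elite].copy()]
            while len(new) < cfg.population:
                parents = []
                for _ in range(2):
                    i, j = rng.integers(0, cfg.population, size=2)
                    parents.append(pop[i if scores[i] <= scores[j] else j])
                c1, c2 = parents[0].copy(), parents[1].copy()
                if rng.random() < cfg.crossover_prob and p > 1:
                    cut = int(rng.integers(1, p))
                    c1[cut:], c2[cut:] = parents[1][cut:], parents[0][cut:]
                for c in (c1, c2):
                    flips = rng.random(p) < cfg.mutation_prob
                    c ^= flips
                    _repair(c, cfg, rng)
                    if len(new) < cfg.population:
                        new.append(c)
            pop = np.array(new)
            scores = np.array([fitness(b) for b in pop])
            history[r, gen] = float(scores.min())
        idx = int(np.argmin(scores))
        # running best: the elite guarantees the trace is non-increasing
        history[r] = np.minimum.accumulate(history[r])
        if scores[idx] < best_g:
            best_g, best_bits, winner = float(scores[idx]), pop[idx].copy(), r
    return GAResult(indices=np.flatnonzero(best_bits), G=best_g,
                    history=history, winner=winner)


def selection_report(result, wavenumbers) -> pd.DataFrame:
    """Selected wavenumbers in cm^-1 (descending), with the achieved G."""
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    wn = np.sort(wavenumbers[np.asarray(result.indices, int)])[::-1]
    return pd.DataFrame(
        {
            "wavenumber_cm1": wn,
            "n_selected": len(wn),
            "G": result.G,
        }
    )


# --- internal stratified hold-out used by the selector transformers -------

def _stratified_holdout(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Per-class round(fraction * n_k) validation indices, >= 1 train kept."""
    y = np.asarray(y)
    train, valid = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)
        k = int(round(fraction * idx.size))
        k = min(k, idx.size - 1)  # keep at least one training sample
        valid.extend(idx[:k])
        train.extend(idx[k:])
    return np.sort(np.asarray(train, int)), np.sort(np.asarray(valid, int))


class _BaseGSelector(TransformerMixin, BaseEstimator):
    """Shared fit plumbing: carve an internal split, run the search."""

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X, dtype=float)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


class SPASelector(_BaseGSelector):
    """SPA wavenumber selection as a Pipeline-compatible transformer.

    An internal stratified hold-out (default 30%) of the data passed to
    ``fit`` provides the validation spectra for G.
    """

    def __init__(self, max_vars: int = 6, covariance_mode: str = "pooled",
                 val_fraction: float = 0.3, random_state: int = 0, starts=None):
        self.max_vars = max_vars
        self.covariance_mode = covariance_mode
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.starts = starts

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        tr, va = _stratified_holdout(y, self.val_fraction, rng)
        res = spa_select(X[tr], y[tr], X[va], y[va],
                         max_vars=min(self.max_vars, X.shape[1]),
                         covariance_mode=self.covariance_mode,
                         starts=self.starts)
        self.result_ = res
        self.support_ = np.sort(res.indices)
        return self


class GASelector(_BaseGSelector):
    """GA wavenumber selection as a Pipeline-compatible transformer."""

    def __init__(self, config: GAConfig | None = None,
                 covariance_mode: str = "pooled", val_fraction: float = 0.3,
                 random_state: int = 0):
        self.config = config
        self.covariance_mode = covariance_mode
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        tr, va = _stratified_holdout(y, self.val_fraction, rng)
        res = ga_select(X[tr], y[tr], X[va], y[va],
                        cfg=self.config, covariance_mode=self.covariance_mode,
                        seed=rng.integers(2**31))
        self.result_ = res
        self.support_ = np.sort(res.indices)
        return self
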