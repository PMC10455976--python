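"""Model validation: Monte Carlo cross-validation, figures of merit,
bootstrap misclassification probability, Mann-Whitney band confirmation.

Monte Carlo cross-validation repeatedly holds out a stratified random 20%
of the specimens (1000 iterations by default), refits the full model —
including any PCA or wavenumber-selection front-end — on the remaining
80%, and predicts the held-out specimens.  Counts are accumulated into a
confusion matrix; per-iteration sensitivities, specificities and F-scores
are summarised by their mean and standard deviation.

Figures of merit are computed one-vs-rest per class:

    SENS = TP / (TP + FN) * 100
    SPEC = TN / (TN + FP) * 100
    F    = 2 * SENS * SPEC / (SENS + SPEC)

and the overall accuracy is 100 * trace / total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from .errors import PlanError
from .io import SpectralDataset, average_replicates

__all__ = [
    "MonteCarloPlan", "ConfusionMatrix", "FiguresOfMerit", "MCCVResult",
    "RobustnessEstimate", "make_splits", "run_mccv", "figures_of_merit",
    "fscore", "bootstrap_misclassification", "mann_whitney_bands",
]


def ordered_classes(y) -> tuple:
    """Distinct labels of ``y``, in disease-progression order when all are
    known histological classes, alphabetical otherwise."""
    from .io import CLASS_LABELS

    present = set(np.asarray(y).tolist())
    if present <= set(CLASS_LABELS):
        return tuple(c for c in CLASS_LABELS if c in present)
    return tuple(np.unique(np.asarray(y)))


@dataclass
class MonteCarloPlan:
    """Stratified repeated hold-out: fraction held out, number of iterations."""

    hold_out_fraction: float = 0.20
    iterations: int = 1000
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hold_out_fraction < 1.0:
            raise PlanError("hold_out_fraction must be in (0, 1)")
        if self.iterations < 1:
            raise PlanError("iterations must be >= 1")


def make_splits(labels, plan: MonteCarloPlan):
    """Yield ``plan.iterations`` reproducible (train, validation) index pairs.

    With stratification each class contributes ``round(fraction * n_k)``
    held-out samples per iteration (at least one training sample always
    retained per class).  Raises :class:`PlanError` if stratification meets
    a singleton class or if no sample at all would be held out.
    """
    y = np.asarray(labels)
    n = y.size
    rng = np.random.default_rng(plan.seed)
    classes = np.unique(y)
    if plan.stratified:
        sizes = {c: int(np.sum(y == c)) for c in classes}
        singles = [c for c, s in sizes.items() if s < 2]
        if singles:
            raise PlanError(
                f"classes {singles} have a single sample; stratified "
                "hold-out cannot keep one in training and one out"
            )
        holds = {c: min(int(round(plan.hold_out_fraction * s)), s - 1)
                 for c, s in sizes.items()}
        if sum(holds.values()) == 0:
            raise PlanError("hold-out fraction too small: empty validation sets")
    else:
        k = int(round(plan.hold_out_fraction * n))
        if k == 0:
            raise PlanError("hold-out fraction too small: empty validation sets")

    splits = []
    for _ in range(plan.iterations):
        if plan.stratified:
            va = []
            for c in classes:
                idx = rng.permutation(np.flatnonzero(y == c))
                va.extend(idx[: holds[c]])
            va = np.sort(np.asarray(va, int))
        else:
            va = np.sort(rng.choice(n, size=k, replace=False))
        tr = np.setdiff1d(np.arange(n), va)
        splits.append((tr, va))
    return splits


@dataclass
class ConfusionMatrix:
    """Square count table; rows = true class, columns = predicted class."""

    classes: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        K = len(self.classes)
        if self.counts.shape != (K, K):
            raise ValueError("counts must be square, one row per class")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def one_vs_rest(self, k: int) -> tuple[float, float, float, float]:
        """(TP, FN, FP, TN) for class index ``k``."""
        c = self.counts
        tp = c[k, k]
        fn = c[k].sum() - tp
        fp = c[:, k].sum() - tp
        tn = c.sum() - tp - fn - fp
        return tp, fn, fp, tn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def fscore(sens: float, spec: float) -> float:
    """Harmonic mean of sensitivity and specificity (both in percent)."""
    if sens == 0.0 and spec == 0.0:
        return 0.0
    return 2.0 * sens * spec / (sens + spec)


@dataclass
class FiguresOfMerit:
    """Per-class one-vs-rest figures (percent) and the overall accuracy."""

    classes: tuple
    sensitivity: np.ndarray
    specificity: np.ndarray
    f_score: np.ndarray
    accuracy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sensitivity_pct": self.sensitivity,
                "specificity_pct": self.specificity,
                "f_score_pct": self.f_score,
            },
            index=list(self.classes),
        )


def figures_of_merit(cm: ConfusionMatrix) -> FiguresOfMerit:
    """Sensitivity, specificity and F-score per class, overall accuracy.

    Classes with an empty denominator (never evaluated / never rejected)
    are reported as NaN (undefined), not as zero.
    """
    K = len(cm.classes)
    total = cm.counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    sens = np.full(K, np.nan)
    spec = np.full(K, np.nan)
    f = np.full(K, np.nan)
    for k in range(K):
        tp, fn, fp, tn = cm.one_vs_rest(k)
        if tp + fn > 0:
            sens[k] = 100.0 * tp / (tp + fn)
        if tn + fp > 0:
            spec[k] = 100.0 * tn / (tn + fp)
        if np.isfinite(sens[k]) and np.isfinite(spec[k]):
            f[k] = fscore(sens[k], spec[k])
    accuracy = 100.0 * np.trace(cm.counts) / total
    return FiguresOfMerit(tuple(cm.classes), sens, spec, f, accuracy)


def _largest_remainder_rows(counts: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Rescale each row to sum to its target count, integerised by the
    largest-remainder rule (row sums conserved exactly)."""
    out = np.zeros_like(counts, dtype=int)
    for i, target in enumerate(targets):
        row = counts[i]
        s = row.sum()
        if s <= 0 or target <= 0:
            continue
        scaled = row * (target / s)
        base = np.floor(scaled).astype(int)
        rem = int(target - base.sum())
        if rem > 0:
            order = np.argsort(-(scaled - base))
            base[order[:rem]] += 1
        out[i] = base
    return out


@dataclass
class MCCVResult:
    classes: tuple
    confusion: ConfusionMatrix          # integerised, rows sum to class sizes
    raw_counts: np.ndarray              # accumulated counts over iterations
    fom_mean: FiguresOfMerit
    fom_std: FiguresOfMerit
    n_iterations: int
    n_failures: int


def run_mccv(X, y, model, plan: MonteCarloPlan,
             class_sizes: dict | None = None,
             selection_once: bool = False) -> MCCVResult:
    """Monte Carlo cross-validate a classifier (or Pipeline).

    The model is re-fitted from scratch — PCA / variable selection included
    — inside every iteration, so no information leaks from validation to
    training.  ``selection_once=True`` instead fits all Pipeline steps but
    the last once on the full data (the optimistic legacy protocol) and
    cross-validates only the final classifier.

    Returns the accumulated confusion matrix rescaled so each row sums to
    the class specimen count (largest-remainder integerisation) together
    with the mean and standard deviation of each figure of merit across
    iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = ordered_classes(y)
    lookup = {c: i for i, c in enumerate(classes)}
    K = len(classes)

    if selection_once and hasattr(model, "steps") and len(model.steps) > 1:
        front = clone(model)
        final = front.steps[-1][1]
        from sklearn.pipeline import Pipeline
        head = Pipeline(front.steps[:-1])
        X = head.fit(X, y).transform(X)
        model = final

    splits = make_splits(y, plan)
    raw = np.zeros((K, K))
    sens_all, spec_all, f_all, acc_all = [], [], [], []
    failures = 0
    for tr, va in splits:
        try:
            est = clone(model)
            est.fit(X[tr], y[tr])
            pred = est.predict(X[va])
        except Exception as e:  # noqa: BLE001 — iteration failures are counted
            failures += 1
            warnings.warn(f"MCCV iteration failed: {e}", stacklevel=2)
            if failures > 0.05 * plan.iterations:
                raise RuntimeError(
                    f"more than 5% of MCCV iterations failed ({failures})"
                ) from e
            continue
        it = np.zeros((K, K))
        for t, p in zip(y[va], pred):
            it[lookup[t], lookup[p]] += 1
        raw += it
        fom = figures_of_merit(ConfusionMatrix(classes, it))
        sens_all.append(fom.sensitivity)
        spec_all.append(fom.specificity)
        f_all.append(fom.f_score)
        acc_all.append(fom.accuracy)

    if not acc_all:
        raise RuntimeError("all MCCV iterations failed")

    if class_sizes is None:
        class_sizes = {c: int(np.sum(y == c)) for c in classes}
    targets = np.array([class_sizes[c] for c in classes])
    cm = ConfusionMatrix(classes, _largest_remainder_rows(raw, targets))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = FiguresOfMerit(classes, np.nanmean(sens_all, axis=0),
                              np.nanmean(spec_all, axis=0),
                              np.nanmean(f_all, axis=0),
                              float(np.mean(acc_all)))
        std = FiguresOfMerit(classes, np.nanstd(sens_all, axis=0),
                             np.nanstd(spec_all, axis=0),
                             np.nanstd(f_all, axis=0),
                             float(np.std(acc_all)))
    return MCCVResult(classes, cm, raw, mean, std,
                      n_iterations=len(acc_all), n_failures=failures)


def run_mccv_dataset(ds: SpectralDataset, model, plan: MonteCarloPlan,
                     average: bool = True, **kwargs) -> MCCVResult:
    """Dataset-facing wrapper: optionally average replicates per specimen
    first, then cross-validate on the absorbance matrix."""
    if average:
        ds = average_replicates(ds)
    return run_mccv(ds.absorbance, ds.class_label, model, plan, **kwargs)


@dataclass
class RobustnessEstimate:
    """Out-of-bag bootstrap misclassification probability."""

    probability: float
    replicates: int
    seed: int
    per_specimen: np.ndarray = field(repr=False, default=None)
    n_never_oob: int = 0


def bootstrap_misclassification(X, y, model, replicates: int = 200,
                                seed: int = 0) -> RobustnessEstimate:
    """Bootstrap out-of-bag misclassification probability of a model.

    Each replicate resamples specimens with replacement within each class
    (stratified), fits the model on the resample and predicts the
    out-of-bag specimens.  A specimen's misclassification probability is
    the fraction of replicates in which it was out-of-bag and
    misclassified; the reported estimate is the mean over specimens.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = y.size
    rng = np.random.default_rng(seed)
    mis = np.zeros(n)
    oob_count = np.zeros(n)
    class_idx = {c: np.flatnonzero(y == c) for c in np.unique(y)}
    for _ in range(replicates):
        boot = np.concatenate(
            [rng.choice(idx, size=idx.size, replace=True)
             for idx in class_idx.values()]
        )
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        est = clone(model)
        try:
            est.fit(X[boot], y[boot])
            pred = est.predict(X[oob])
        except Exception as e:  # noqa: BLE001
            warnings.warn(f"bootstrap replicate failed: {e}", stacklevel=2)
            continue
        wrong = pred != y[oob]
        mis[oob] += wrong
        oob_count[oob] += 1
    covered = oob_count > 0
    n_never = int(np.sum(~covered))
    if n_never:
        warnings.warn(
            f"{n_never} specimens were never out-of-bag and are excluded",
            stacklevel=2,
        )
    if not covered.any():
        raise RuntimeError("no specimen was ever out-of-bag")
    per_spec = np.full(n, np.nan)
    per_spec[covered] = mis[covered] / oob_count[covered]
    return RobustnessEstimate(
        probability=float(np.nanmean(per_spec)),
        replicates=replicates,
        seed=seed,
        per_specimen=per_spec,
        n_never_oob=n_never,
    )


def mann_whitney_bands(ds: SpectralDataset, variables, class_pair,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Two-tailed Mann-Whitney rank test per selected wavenumber.

    Compares the preprocessed absorbances of two classes at each selected
    wavenumber.  The exact null distribution is used for small groups
    (both n <= 8), the normal approximation with tie correction otherwise.
    Constant values across both groups give p = 1 with a flag.
    """
    a, b = class_pair
    ia = np.flatnonzero(ds.class_label == a)
    ib = np.flatnonzero(ds.class_label == b)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("both classes need >= 2 spectra")
    variables = np.asarray(variables, dtype=int)
    rows = []
    for v in variables:
        xa = ds.absorbance[ia, v]
        xb = ds.absorbance[ib, v]
        if np.ptp(np.concatenate([xa, xb])) == 0:
            rows.append((ds.wavenumbers[v], np.nan, 1.0, False, True))
            continue
        method = "exact" if max(ia.size, ib.size) <= 8 else "asymptotic"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        rows.append((ds.wavenumbers[v], float(res.statistic),
                     float(res.pvalue), res.pvalue < alpha, False))
    return pd.DataFrame(
        rows,
        columns=["wavenumber_cm1", "U", "p_value", "significant", "degenerate"],
    )
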