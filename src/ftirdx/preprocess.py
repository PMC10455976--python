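"""Spectral pre-treatment: fingerprint cut, rubber-band baseline, amide-I norm.

The chain mirrors standard ATR-FTIR practice for tissue spectra:

1. **cut** — truncate to the biochemical fingerprint region, by default the
   closed interval [900, 1800] cm^-1;
2. **baseline** — rubber-band correction: subtract the lower convex hull of
   each spectrum, stretched between its endpoints, removing broad drift
   while preserving peaks;
3. **normalise** — divide by the maximum absorbance inside the amide I
   window (1600-1700 cm^-1), the dominant protein band, so spectra become
   comparable across contact pressure and sample thickness.

Each step is exposed both as a scikit-learn transformer operating on plain
``(n_spectra, n_wavenumbers)`` arrays (composable with ``sklearn.pipeline``)
and as a function on :class:`~ftirdx.io.SpectralDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, DegenerateSpectrumError, IntervalError
from .io import SpectralDataset, validate_axis

# relative slack when comparing wavenumbers to interval edges, to keep the
# closed-interval semantics robust to floating-point grid construction
_EDGE_RTOL = 1e-9


@dataclass
class PreprocessConfig:
    """Configuration of the pre-treatment chain.

    ``steps`` is an ordered subset of {"cut", "baseline", "normalise"};
    the default order is the full chain.
    """

    cut_low: float = 900.0
    cut_high: float = 1800.0
    amide_low: float = 1600.0
    amide_high: float = 1700.0
    steps: tuple[str, ...] = ("cut", "baseline", "normalise")

    def __post_init__(self) -> None:
        if not self.steps:
            raise ConfigError("steps must be non-empty")
        unknown = set(self.steps) - {"cut", "baseline", "normalise"}
        if unknown:
            raise ConfigError(f"unknown preprocessing steps {sorted(unknown)}")
        if not self.cut_low < self.cut_high:
            raise ConfigError("cut_low must be < cut_high")
        if not (self.cut_low <= self.amide_low < self.amide_high <= self.cut_high):
            raise ConfigError("amide window must lie inside the cut window")


def _window_mask(wavenumbers: np.ndarray, low: float, high: float) -> np.ndarray:
    tol = _EDGE_RTOL * max(abs(low), abs(high), 1.0)
    return (wavenumbers >= low - tol) & (wavenumbers <= high + tol)


def cut_axis(wavenumbers: np.ndarray, low: float, high: float) -> np.ndarray:
    """Boolean mask of axis points inside the closed interval [low, high]."""
    mask = _window_mask(np.asarray(wavenumbers, float), low, high)
    if not mask.any():
        raise IntervalError(
            f"interval [{low}, {high}] cm^-1 selects no axis points "
            f"(axis spans [{wavenumbers.min():g}, {wavenumbers.max():g}])"
        )
    return mask


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull vertices of the points (x, y).

    ``x`` must be strictly increasing.  Andrew's monotone-chain scan; strictly
    negative cross products only, so collinear interior points are kept off
    the vertex list (they still lie on the baseline exactly).
    """
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (x[i] - x[i1]) * (y[i2] - y[i1])
            if cross <= 0:  # hull[-1] is above or on the chord: drop it
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull)


def rubber_band_baseline(spectrum: np.ndarray, wavenumbers: np.ndarray) -> np.ndarray:
    """Subtract the rubber-band baseline from one spectrum.

    The baseline is the lower convex hull of the points
    ``(wavenumber, absorbance)`` evaluated between the two spectral
    endpoints (piecewise linear through the hull's lower vertices).  The
    corrected spectrum is non-negative, and exactly zero at both endpoints
    and at every hull vertex.
    """
    y = np.asarray(spectrum, dtype=float)
    wn = np.asarray(wavenumbers, dtype=float)
    if y.size != wn.size:
        raise ValueError("spectrum and axis lengths differ")
    if y.size < 3:
        raise ValueError("rubber-band correction needs >= 3 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite absorbance values")
    # work on an ascending axis regardless of storage direction
    if wn[0] > wn[-1]:
        flip = True
        x_asc, y_asc = wn[::-1], y[::-1]
    else:
        flip = False
        x_asc, y_asc = wn, y
    hull = _lower_hull_indices(x_asc, y_asc)
    baseline = np.interp(x_asc, x_asc[hull], y_asc[hull])
    out = y_asc - baseline
    out[hull] = 0.0  # exact zeros at the supporting vertices
    np.maximum(out, 0.0, out=out)
    return out[::-1].copy() if flip else out


def normalise_amide_i(
    spectrum: np.ndarray,
    wavenumbers: np.ndarray,
    window: tuple[float, float] = (1600.0, 1700.0),
) -> np.ndarray:
    """Scale a spectrum so its maximum inside the amide I window equals 1."""
    y = np.asarray(spectrum, dtype=float)
    mask = cut_axis(np.asarray(wavenumbers, float), window[0], window[1])
    peak = y[mask].max()
    if peak <= 0:
        raise DegenerateSpectrumError(
            f"maximum absorbance in the {window} cm^-1 window is {peak:g}; "
            "cannot normalise"
        )
    return y / peak


class FingerprintCut(BaseEstimator, TransformerMixin):
    """Truncate spectra to a closed wavenumber interval.

    Parameters
    ----------
    wavenumbers : axis the input columns are aligned to.
    low, high : interval bounds in cm^-1 (defaults: fingerprint region).
    """

    def __init__(self, wavenumbers=None, low: float = 900.0, high: float = 1800.0):
        self.wavenumbers = wavenumbers
        self.low = low
        self.high = high

    def fit(self, X, y=None):
        wn = validate_axis(self.wavenumbers)
        self.mask_ = cut_axis(wn, self.low, self.high)
        self.wavenumbers_ = wn[self.mask_]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X[:, self.mask_]


class RubberBandBaseline(BaseEstimator, TransformerMixin):
    """Row-wise rubber-band (lower convex hull) baseline correction."""

    def __init__(self, wavenumbers=None):
        self.wavenumbers = wavenumbers

    def fit(self, X, y=None):
        self.wavenumbers_ = validate_axis(self.wavenumbers)
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack(
            [rubber_band_baseline(row, self.wavenumbers_) for row in X]
        )


class AmideINormalizer(BaseEstimator, TransformerMixin):
    """Row-wise peak-height normalisation to the amide I window maximum."""

    def __init__(self, wavenumbers=None, window: tuple[float, float] = (1600.0, 1700.0)):
        self.wavenumbers = wavenumbers
        self.window = window

    def fit(self, X, y=None):
        self.wavenumbers_ = validate_axis(self.wavenumbers)
        self.mask_ = cut_axis(self.wavenumbers_, self.window[0], self.window[1])
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        peaks = X[:, self.mask_].max(axis=1)
        if np.any(peaks <= 0):
            bad = int(np.argmax(peaks <= 0))
            raise DegenerateSpectrumError(
                f"spectrum {bad}: amide I window maximum {peaks[bad]:g} <= 0"
            )
        return X / peaks[:, None]


# --- dataset-level chain -------------------------------------------------

def cut(ds: SpectralDataset, low: float = 900.0, high: float = 1800.0) -> SpectralDataset:
    """Truncate a dataset to the closed interval [low, high] cm^-1."""
    mask = cut_axis(ds.wavenumbers, low, high)
    return SpectralDataset(
        ds.wavenumbers[mask],
        ds.absorbance[:, mask],
        ds.specimen_id,
        ds.replicate,
        ds.class_label,
    )


def preprocess_pipeline(ds: SpectralDataset, cfg: PreprocessConfig | None = None) -> SpectralDataset:
    """Apply the configured pre-treatment steps, in order, to every record."""
    cfg = cfg or PreprocessConfig()
    if ds.n_spectra == 0:
        raise ValueError("empty dataset")
    out = ds
    for step in cfg.steps:
        try:
            if step == "cut":
                out = cut(out, cfg.cut_low, cfg.cut_high)
            elif step == "baseline":
                corrected = np.vstack(
                    [rubber_band_baseline(row, out.wavenumbers) for row in out.absorbance]
                )
                out = SpectralDataset(out.wavenumbers, corrected, out.specimen_id,
                                      out.replicate, out.class_label)
            elif step == "normalise":
                rows = []
                for i, row in enumerate(out.absorbance):
                    try:
                        rows.append(
                            normalise_amide_i(row, out.wavenumbers,
                                              (cfg.amide_low, cfg.amide_high))
                        )
                    except DegenerateSpectrumError as e:
                        raise DegenerateSpectrumError(
                            f"specimen {out.specimen_id[i]!r} replicate "
                            f"{int(out.replicate[i])}: {e}"
                        ) from e
                out = SpectralDataset(out.wavenumbers, rows, out.specimen_id,
                                      out.replicate, out.class_label)
        except (DegenerateSpectrumError, IntervalError) as e:
            raise type(e)(f"step {step!r}: {e}") from e
    return out
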