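"""Synthetic six-class ATR-FTIR tissue spectra.

Generates absorbance spectra with the statistical structure the analysis
pipeline assumes: six ordered histological classes (normal, inflammatory,
Barrett's, LGD, HGD, OAC) with unbalanced specimen counts (35/13/26/4/9/22
by default), ten replicate point spectra per specimen, on a 4000-600 cm^-1
grid at 300/78 ~ 3.846 cm^-1 spacing (an 8 cm^-1-resolution instrument
with 2x zero filling), so that the [900, 1800] cm^-1 fingerprint cut
retains exactly 235 wavenumbers.

Each spectrum is a sum of Gaussian absorption bands at wavenumbers with
established tissue assignments — 1745 (lipid ester C=O), 1690 (nucleic
acid base carbonyl), 1640 (amide I), 1540 (amide II), 1393 (methylene
deformation) and 1225 cm^-1 (asymmetric phosphate stretch) — plus a random
linear/quadratic baseline drift, a multiplicative gain and additive white
noise per replicate.  Class identity enters through small per-class shifts
of the band amplitudes, with a monotone disease-stage trend on the nucleic
acid and phosphate bands:

* ``separation`` (s >= 0) scales all between-class amplitude differences
  (s = 0: all classes identical; s = 10: strongly separable);
* ``overlap`` (o in [0, 1]) pulls the inflammatory class's amplitude means
  toward the normal class's (o = 1: the two are identical), reproducing
  the characteristic normal/inflammatory confusion of tissue studies.

Specimen-to-specimen biological variation is log-normal per band; the
amide I amplitude is identical across classes so that peak normalisation
is well-posed and carries no class information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .io import CLASS_LABELS, SpectralDataset

#: default per-class specimen counts, in disease-progression order
DEFAULT_CLASS_SIZES: tuple[int, ...] = (35, 13, 26, 4, 9, 22)

#: axis of 885 points from 4000 down to 600 cm^-1 (spacing 300/78 cm^-1)
AXIS_POINTS = 885


def default_axis() -> np.ndarray:
    return np.linspace(4000.0, 600.0, AXIS_POINTS)


@dataclass
class BandSpec:
    """One Gaussian absorption band.

    ``base_amplitude`` is the class-average amplitude; ``class_deltas`` are
    the per-class deviations (progression order) that the generator scales
    by the separation factor.
    """

    centre: float
    width: float                      # Gaussian sigma, cm^-1
    base_amplitude: float
    class_deltas: tuple[float, ...]
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError("band width must be positive")
        if self.base_amplitude < 0:
            raise ConfigError("band amplitude must be non-negative")
        if len(self.class_deltas) != len(CLASS_LABELS):
            raise ConfigError("one amplitude delta per class required")

    @property
    def discriminative(self) -> bool:
        return len(set(self.class_deltas)) > 1


def default_band_library() -> list[BandSpec]:
    """The six-band library used by the default generator configuration.

    Amide I dominates the 1600-1700 cm^-1 window in every class and carries
    no class signal; the nucleic-acid (1690) and phosphate (1225) bands
    carry a monotone disease-stage trend; the remaining bands carry small,
    mutually distinct class patterns.
    """
    return [
        BandSpec(1745.0, 8.0, 0.15,
                 (0.010, 0.007, -0.004, -0.004, -0.004, -0.005),
                 "lipid ester C=O stretch (high in benign epithelium)"),
        BandSpec(1690.0, 10.0, 0.25,
                 (-0.012, -0.006, -0.002, 0.002, 0.007, 0.013),
                 "nucleic acid base carbonyl / ring breathing (stage trend)"),
        BandSpec(1640.0, 16.0, 1.00,
                 (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
                 "amide I (protein C=O stretch; normalisation reference)"),
        BandSpec(1540.0, 12.0, 0.55,
                 (-0.010, 0.006, 0.014, -0.006, -0.002, -0.002),
                 "amide II (protein N-H bend / C-N stretch)"),
        BandSpec(1393.0, 10.0, 0.30,
                 (0.004, -0.004, 0.002, -0.012, 0.010, -0.006),
                 "methylene deformation"),
        BandSpec(1225.0, 14.0, 0.35,
                 (-0.010, -0.008, -0.005, 0.000, 0.006, 0.017),
                 "asymmetric phosphate stretch (stage trend)"),
    ]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-spectra generator.

    Noise magnitudes are in the absorbance units in which the amide I band
    has amplitude ~1.
    """

    class_sizes: tuple[int, ...] = DEFAULT_CLASS_SIZES
    replicates: int = 10
    bands: list[BandSpec] = field(default_factory=default_band_library)
    separation: float = 5.0
    overlap: float = 0.8
    amplitude_cv: float = 0.025       # specimen-level log-normal sigma per band
    gain_sd: float = 0.02             # replicate multiplicative gain spread
    baseline_offset_sd: float = 0.01
    baseline_linear_sd: float = 0.02
    baseline_quadratic_sd: float = 0.01
    noise_sd: float = 0.004           # additive white noise per point
    seed: int = 0
    axis: np.ndarray = field(default_factory=default_axis)

    def __post_init__(self) -> None:
        if len(self.class_sizes) != len(CLASS_LABELS):
            raise ConfigError("class_sizes must have six entries")
        if any(s < 0 for s in self.class_sizes):
            raise ConfigError("class sizes must be >= 0")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.separation < 0:
            raise ConfigError("separation must be >= 0")
        if not 0.0 <= self.overlap <= 1.0:
            raise ConfigError("overlap must lie in [0, 1]")
        for name in ("amplitude_cv", "gain_sd", "baseline_offset_sd",
                     "baseline_linear_sd", "baseline_quadratic_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = float(np.min(self.axis)), float(np.max(self.axis))
        for b in self.bands:
            if not lo <= b.centre <= hi:
                raise ConfigError(
                    f"band centre {b.centre} cm^-1 outside axis [{lo}, {hi}]"
                )


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    specimen_id: np.ndarray
    class_label: np.ndarray
    band_amplitudes: np.ndarray       # (n_specimens, n_bands) true amplitudes
    band_centres: np.ndarray
    discriminative: np.ndarray        # bool per band
    config: GeneratorConfig


def class_amplitude_means(cfg: GeneratorConfig) -> np.ndarray:
    """(n_classes, n_bands) band amplitude means after overlap + separation."""
    K = len(CLASS_LABELS)
    amp = np.empty((K, len(cfg.bands)))
    for j, band in enumerate(cfg.bands):
        deltas = np.asarray(band.class_deltas, dtype=float).copy()
        # overlap pulls inflammatory (index 1) toward normal (index 0)
        deltas[1] = (1.0 - cfg.overlap) * deltas[1] + cfg.overlap * deltas[0]
        amp[:, j] = band.base_amplitude + cfg.separation * deltas
    if np.any(amp < 0):
        raise ConfigError(
            "separation too large: a band amplitude went negative"
        )
    return amp


def generate(cfg: GeneratorConfig | None = None) -> tuple[SpectralDataset, SyntheticTruth]:
    """Draw a synthetic dataset; deterministic for a given config and seed."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    axis = np.asarray(cfg.axis, dtype=float)
    t = (axis - axis.min()) / (axis.max() - axis.min())  # [0,1] for baselines
    centres = np.array([b.centre for b in cfg.bands])
    widths = np.array([b.width for b in cfg.bands])
    profiles = np.exp(-((axis[None, :] - centres[:, None]) ** 2)
                      / (2.0 * widths[:, None] ** 2))  # (n_bands, n_points)
    amp_means = class_amplitude_means(cfg)

    labels_per_specimen: list[str] = []
    for c, size in zip(CLASS_LABELS, cfg.class_sizes):
        labels_per_specimen.extend([c] * size)
    n_spec = len(labels_per_specimen)
    if n_spec == 0:
        raise ConfigError("no specimens requested")
    order = rng.permutation(n_spec)
    labels = np.array(labels_per_specimen, dtype=object)[order]
    class_index = {c: k for k, c in enumerate(CLASS_LABELS)}

    sids = np.array([f"S{i + 1:03d}" for i in range(n_spec)], dtype=object)
    spec_amps = np.empty((n_spec, len(cfg.bands)))
    rows, row_sid, row_rep, row_lab = [], [], [], []
    for i in range(n_spec):
        k = class_index[labels[i]]
        amps = amp_means[k] * np.exp(rng.normal(0.0, cfg.amplitude_cv,
                                                size=len(cfg.bands)))
        spec_amps[i] = amps
        clean = amps @ profiles
        for rep in range(1, cfg.replicates + 1):
            gain = 1.0 + rng.normal(0.0, cfg.gain_sd)
            b0 = rng.normal(0.0, cfg.baseline_offset_sd)
            b1 = rng.normal(0.0, cfg.baseline_linear_sd)
            b2 = rng.normal(0.0, cfg.baseline_quadratic_sd)
            noise = rng.normal(0.0, cfg.noise_sd, size=axis.size)
            rows.append(gain * clean + b0 + b1 * t + b2 * t * t + noise)
            row_sid.append(sids[i])
            row_rep.append(rep)
            row_lab.append(labels[i])

    ds = SpectralDataset(axis, np.vstack(rows), np.array(row_sid, dtype=object),
                         np.array(row_rep), np.array(row_lab, dtype=object))
    truth = SyntheticTruth(
        specimen_id=sids,
        class_label=labels,
        band_amplitudes=spec_amps,
        band_centres=centres,
        discriminative=np.array([b.discriminative for b in cfg.bands]),
        config=cfg,
    )
    return ds, truth


def truth_recovery_report(truth: SyntheticTruth, selected_indices,
                          wavenumbers) -> "pd.DataFrame":
    """Distance of each selected wavenumber to the nearest discriminative
    band centre, with the median as a selection-quality summary."""
    import pandas as pd

    idx = np.asarray(selected_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("selection is empty")
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    centres = truth.band_centres[truth.discriminative]
    if centres.size == 0:
        raise ValueError("no discriminative bands in the truth object")
    sel_wn = wavenumbers[idx]
    dist = np.abs(sel_wn[:, None] - centres[None, :]).min(axis=1)
    df = pd.DataFrame({"wavenumber_cm1": sel_wn, "distance_cm1": dist})
    df.attrs["median_distance_cm1"] = float(np.median(dist))
    return df
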