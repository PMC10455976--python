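"""Labelled spectral datasets and delimited-text I/O.

The central container is :class:`SpectralDataset`: a shared wavenumber axis
(cm^-1, stored descending by instrument convention), an absorbance matrix
with one row per spectrum, and per-spectrum metadata (specimen id, replicate
index, histological class).  Six ordered classes are supported, covering the
progression from normal squamous epithelium to oesophageal adenocarcinoma.

Two plain-text layouts are read and written:

* ``wide``  — three metadata header rows (``specimen_id``, ``replicate``,
  ``class``) followed by one row per wavenumber; first column holds the
  wavenumber, each remaining column one spectrum.
* ``long``  — tidy table with columns
  ``specimen_id,replicate,class,wavenumber,absorbance``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AxisError, FormatError, LabelError

#: The closed, ordered set of histological classes (disease progression order).
CLASS_LABELS: tuple[str, ...] = (
    "normal",
    "inflammatory",
    "barretts",
    "lgd",
    "hgd",
    "oac",
)

_AXIS_UNIFORMITY_TOL = 0.01  # spacing spread allowed, fraction of median spacing


def validate_axis(values: np.ndarray) -> np.ndarray:
    """Validate a wavenumber axis and return it stored descending.

    The axis must be strictly monotone (either direction accepted), all
    positive, and near-uniform: the spread of consecutive spacings may not
    exceed 1% of the median spacing.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise AxisError("wavenumber axis must be a 1-D array with >= 2 points")
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise AxisError("wavenumbers must be finite and positive")
    d = np.diff(v)
    if np.all(d > 0):
        v = v[::-1].copy()
        d = -d[::-1]
    elif not np.all(d < 0):
        raise AxisError("wavenumber axis must be strictly monotone")
    spacing = -d
    med = np.median(spacing)
    if np.max(np.abs(spacing - med)) > _AXIS_UNIFORMITY_TOL * med:
        raise AxisError("wavenumber grid is not near-uniform (>1% spacing spread)")
    return v


@dataclass
class SpectralDataset:
    """A labelled set of spectra on a common descending wavenumber axis.

    Attributes
    ----------
    wavenumbers : (p,) float array, strictly descending, cm^-1.
    absorbance : (n, p) float array, one spectrum per row.
    specimen_id : (n,) array of opaque specimen identifiers.
    replicate : (n,) int array, replicate index >= 1 within each specimen.
    class_label : (n,) array of labels from :data:`CLASS_LABELS`.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    specimen_id: np.ndarray
    replicate: np.ndarray
    class_label: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = validate_axis(self.wavenumbers)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.specimen_id = np.asarray(self.specimen_id, dtype=object)
        self.replicate = np.asarray(self.replicate, dtype=int)
        self.class_label = np.asarray(self.class_label, dtype=object)
        n, p = self.absorbance.shape
        if p != self.wavenumbers.size:
            raise FormatError(
                f"absorbance has {p} columns but the axis has "
                f"{self.wavenumbers.size} points"
            )
        for name, arr in (
            ("specimen_id", self.specimen_id),
            ("replicate", self.replicate),
            ("class_label", self.class_label),
        ):
            if arr.shape != (n,):
                raise FormatError(f"{name} length {arr.shape} != number of spectra {n}")
        if not np.all(np.isfinite(self.absorbance)):
            raise FormatError("absorbance contains non-finite values")
        bad = set(self.class_label) - set(CLASS_LABELS)
        if bad:
            raise LabelError(
                f"unknown class labels {sorted(map(str, bad))}; "
                f"allowed: {list(CLASS_LABELS)}"
            )
        if np.any(self.replicate < 1):
            raise FormatError("replicate indices must be >= 1")
        pairs = list(zip(self.specimen_id, self.replicate))
        if len(set(pairs)) != n:
            raise FormatError("duplicate (specimen_id, replicate) pairs")

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.wavenumbers.size

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            self.wavenumbers.copy(),
            self.absorbance.copy(),
            self.specimen_id.copy(),
            self.replicate.copy(),
            self.class_label.copy(),
        )

    def select_records(self, idx) -> "SpectralDataset":
        """Row-subset the dataset (axis shared, metadata carried along)."""
        idx = np.asarray(idx)
        return SpectralDataset(
            self.wavenumbers,
            self.absorbance[idx],
            self.specimen_id[idx],
            self.replicate[idx],
            self.class_label[idx],
        )

    def y(self) -> np.ndarray:
        """Class labels as an object array (alias used by model code)."""
        return self.class_label

    def equals(self, other: "SpectralDataset", atol: float = 1e-9) -> bool:
        return (
            np.allclose(self.wavenumbers, other.wavenumbers, atol=atol)
            and self.absorbance.shape == other.absorbance.shape
            and np.allclose(self.absorbance, other.absorbance, atol=atol)
            and np.array_equal(self.specimen_id, other.specimen_id)
            and np.array_equal(self.replicate, other.replicate)
            and np.array_equal(self.class_label, other.class_label)
        )


def read_dataset(path, layout: str = "wide") -> SpectralDataset:
    """Read a dataset from a delimited text file.

    Parameters
    ----------
    path : file path.
    layout : ``"wide"`` or ``"long"`` (see module docstring).
    """
    if layout == "wide":
        return _read_wide(path)
    if layout == "long":
        return _read_long(path)
    raise ValueError(f"unknown layout {layout!r}")


def _read_wide(path) -> SpectralDataset:
    try:
        raw = pd.read_csv(path, header=None, dtype=str)
    except pd.errors.ParserError as e:  # ragged rows
        raise FormatError(f"cannot parse {path}: {e}") from e
    if raw.shape[0] < 4 or raw.shape[1] < 2:
        raise FormatError("wide file needs 3 header rows, >=1 wavenumber row, >=1 spectrum")
    header_names = [str(x).strip() for x in raw.iloc[:3, 0]]
    if header_names != ["specimen_id", "replicate", "class"]:
        raise FormatError(
            "wide header rows must be specimen_id / replicate / class, got "
            f"{header_names}"
        )
    specimen_id = raw.iloc[0, 1:].to_numpy(dtype=object)
    try:
        replicate = raw.iloc[1, 1:].astype(int).to_numpy()
    except (TypeError, ValueError) as e:
        raise FormatError(f"non-integer replicate row: {e}") from e
    class_label = raw.iloc[2, 1:].to_numpy(dtype=object)
    if any(pd.isna(c) or str(c).strip() == "" for c in class_label):
        raise LabelError("missing class label in header")
    class_label = np.array([str(c).strip() for c in class_label], dtype=object)
    body = raw.iloc[3:, :]
    try:
        values = body.astype(float).to_numpy()
    except (TypeError, ValueError) as e:
        raise FormatError(f"non-numeric absorbance or wavenumber: {e}") from e
    if np.any(pd.isna(values)):
        raise FormatError("missing values in spectral block")
    wavenumbers = values[:, 0]
    absorbance = values[:, 1:].T  # spectra as rows
    ds = SpectralDataset(wavenumbers, absorbance, specimen_id, replicate, class_label)
    # validate_axis may have flipped an ascending file to descending storage
    if wavenumbers[0] < wavenumbers[-1]:
        ds.absorbance = ds.absorbance[:, ::-1].copy()
    return ds


def _read_long(path) -> SpectralDataset:
    df = pd.read_csv(path, dtype={"specimen_id": str, "class": str})
    required = ["specimen_id", "replicate", "class", "wavenumber", "absorbance"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"long file missing columns {missing}")
    if df["class"].isna().any():
        raise LabelError("missing class label")
    if df[["wavenumber", "absorbance"]].isna().any().any():
        raise FormatError("missing numeric values in long file")
    key = ["specimen_id", "replicate", "class"]
    groups = df.groupby(key, sort=False)
    first_axis = None
    rows, sids, reps, labels = [], [], [], []
    for (sid, rep, lab), g in groups:
        axis = g["wavenumber"].to_numpy(dtype=float)
        if first_axis is None:
            first_axis = axis
        elif axis.shape != first_axis.shape or not np.array_equal(axis, first_axis):
            raise FormatError("spectra in long file do not share one wavenumber axis")
        rows.append(g["absorbance"].to_numpy(dtype=float))
        sids.append(sid)
        reps.append(int(rep))
        labels.append(lab)
    if first_axis is None:
        raise FormatError("empty long file")
    absorbance = np.vstack(rows)
    ds = SpectralDataset(first_axis, absorbance, np.array(sids, dtype=object),
                         np.array(reps), np.array(labels, dtype=object))
    if first_axis[0] < first_axis[-1]:
        ds.absorbance = ds.absorbance[:, ::-1].copy()
    return ds


def write_dataset(ds: SpectralDataset, path, layout: str = "wide") -> None:
    """Write a dataset to ``path``; round-trips through :func:`read_dataset`
    to at least 10 significant digits."""
    if ds.n_spectra == 0:
        raise FormatError("refusing to write a dataset with no spectra")
    if layout == "wide":
        _write_wide(ds, path)
    elif layout == "long":
        _write_long(ds, path)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def _fmt(x: float) -> str:
    return format(x, ".12g")


def _write_wide(ds: SpectralDataset, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("specimen_id," + ",".join(str(s) for s in ds.specimen_id) + "\n")
        fh.write("replicate," + ",".join(str(int(r)) for r in ds.replicate) + "\n")
        fh.write("class," + ",".join(str(c) for c in ds.class_label) + "\n")
        for j, wn in enumerate(ds.wavenumbers):
            vals = ",".join(_fmt(a) for a in ds.absorbance[:, j])
            fh.write(f"{_fmt(wn)},{vals}\n")


def _write_long(ds: SpectralDataset, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("specimen_id,replicate,class,wavenumber,absorbance\n")
        for i in range(ds.n_spectra):
            sid, rep, lab = ds.specimen_id[i], int(ds.replicate[i]), ds.class_label[i]
            for j, wn in enumerate(ds.wavenumbers):
                fh.write(f"{sid},{rep},{lab},{_fmt(wn)},{_fmt(ds.absorbance[i, j])}\n")


def average_replicates(ds: SpectralDataset) -> SpectralDataset:
    """Average the replicate point spectra of each specimen.

    Returns one record per specimen (replicate index 1), the arithmetic mean
    of that specimen's replicates.  Specimens appear in order of first
    occurrence.  Raises :class:`LabelError` if a specimen's replicates carry
    conflicting class labels.
    """
    order: list = []
    groups: dict = {}
    for i, sid in enumerate(ds.specimen_id):
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(i)
    means, sids, labels = [], [], []
    for sid in order:
        idx = groups[sid]
        labs = set(ds.class_label[idx])
        if len(labs) != 1:
            raise LabelError(
                f"specimen {sid!r} has conflicting class labels {sorted(labs)}"
            )
        means.append(ds.absorbance[idx].mean(axis=0))
        sids.append(sid)
        labels.append(next(iter(labs)))
    return SpectralDataset(
        ds.wavenumbers,
        np.vstack(means),
        np.array(sids, dtype=object),
        np.ones(len(sids), dtype=int),
        np.array(labels, dtype=object),
    )


def class_counts(ds: SpectralDataset) -> dict[str, int]:
    """Number of distinct specimens per class, every class reported."""
    seen: dict[str, set] = {c: set() for c in CLASS_LABELS}
    for sid, lab in zip(ds.specimen_id, ds.class_label):
        seen[lab].add(sid)
    return {c: len(seen[c]) for c in CLASS_LABELS}
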