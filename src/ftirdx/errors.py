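"""Exception hierarchy for ftirdx.

All package-raised errors derive from :class:`FtirdxError` so callers can
catch pipeline failures with a single except clause while still
distinguishing the failure mode.
"""


class FtirdxError(Exception):
    """Base class for all ftirdx errors."""


class FormatError(FtirdxError):
    """Malformed input file: ragged rows, non-numeric absorbance, bad header."""


class LabelError(FtirdxError):
    """Class label outside the closed six-value set, or missing/conflicting."""


class AxisError(FtirdxError):
    """Wavenumber axis not strictly monotone, non-positive, or non-uniform."""


class IntervalError(FtirdxError):
    """A spectral interval selects no axis points."""


class DegenerateSpectrumError(FtirdxError):
    """A spectrum cannot be normalised (window maximum not positive)."""


class PlanError(FtirdxError):
    """An invalid resampling plan (empty validation sets, singleton classes)."""


class ConfigError(FtirdxError):
    """Invalid configuration values."""


class SingularityError(FtirdxError):
    """A covariance matrix is singular and no regularisation was requested."""
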