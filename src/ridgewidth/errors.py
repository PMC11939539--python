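"""Exception hierarchy for the ridgewidth pipeline.

Every stage raises a subclass of :class:`RidgeWidthError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class RidgeWidthError(Exception):
    """Base class for all pipeline errors."""


class InputError(RidgeWidthError):
    """Missing or unusable input (empty directory, absent file...)."""


class MetadataError(RidgeWidthError):
    """Missing or contradictory image metadata (pixel spacing, voxel size)."""


class SeriesError(RidgeWidthError):
    """DICOM files in one directory belong to more than one series."""


class BoundsError(RidgeWidthError):
    """Index or region outside the volume extent."""


class GeometryError(RidgeWidthError):
    """Measurement-line geometry invalid (zero length, outside the slice)."""


class ParameterError(RidgeWidthError):
    """Parameter outside its valid range."""


class ToleranceError(RidgeWidthError):
    """No axial slice lies within the allowed depth tolerance."""


class CompatibilityError(RidgeWidthError):
    """Two volumes cannot be combined (e.g. differing voxel sizes)."""


class MeasurementError(RidgeWidthError):
    """A position could not be measured (fewer than two grey-value maxima)."""


class PairingError(RidgeWidthError):
    """Two measurement sets cannot be paired (label or length mismatch)."""


class StatsError(RidgeWidthError):
    """Degenerate statistical design (too few groups, subjects or raters)."""


class PhantomSpecError(RidgeWidthError):
    """Inconsistent synthetic-phantom specification."""
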