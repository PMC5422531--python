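"""Exception hierarchy.

Two broad families matter to callers: configuration/usage problems
(:class:`ConfigurationError` and friends, CLI exit code 1) and data/IO
problems (:class:`DataError` and friends, CLI exit code 2).
"""


class HemiasymError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HemiasymError, ValueError):
    """An invalid configuration value; the message names the field."""


class ArgumentError(HemiasymError, ValueError):
    """An invalid argument to an operation."""


class GeometryError(HemiasymError, ValueError):
    """Volume geometries are incompatible or a point is out of bounds."""


class FormatError(HemiasymError, ValueError):
    """A file could not be parsed in the expected format."""


class GenerationError(HemiasymError, RuntimeError):
    """The synthetic generator was asked for an impossible volume."""


class DegenerateRegionError(HemiasymError, RuntimeError):
    """An ROI search region or mask contains no usable voxels."""


class CompletenessError(HemiasymError, KeyError):
    """A subject x ROI table is missing required rows."""


class AssignmentError(HemiasymError, KeyError):
    """A group assignment does not cover every subject."""


class DegenerateSplitError(HemiasymError, ValueError):
    """A median split was requested on constant values."""


class CollinearityError(HemiasymError, ValueError):
    """The ANCOVA design matrix is rank deficient."""


class AlignmentError(HemiasymError, ValueError):
    """Trial onsets do not lie on the scan (TR) grid."""


class DataError(HemiasymError, ValueError):
    """Inconsistent trial or behavioral data."""
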