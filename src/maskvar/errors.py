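"""Exception hierarchy.

The CLI maps :class:`ConfigError`/`UsageError` to exit code 2 and
:class:`DataError`/`FormatError` to exit code 3.
"""


class MaskvarError(Exception):
    """Base class for all package errors."""


class FormatError(MaskvarError):
    """A file does not conform to its expected format (DICOM tag missing,
    JSON schema violation, malformed coordinate triplets, ...)."""


class DataError(MaskvarError):
    """Input data is well-formed but semantically invalid (non-planar
    contour, degenerate polygon, empty mask, mismatched label sets)."""


class ConfigError(MaskvarError):
    """A configuration value is out of range or inconsistent."""


class UsageError(MaskvarError):
    """An API was called with arguments that violate its contract."""


class ShapeError(MaskvarError):
    """Two gridded objects that must share a geometry do not."""
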