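"""Exception hierarchy.

Config problems (bad parameters, bad run files) and data problems (bad
input values, degenerate spectra) are kept apart so the CLI can map them
to distinct exit codes (2 and 3 respectively).
"""


class SproutspecError(Exception):
    """Base class for all package errors."""


class ConfigError(SproutspecError):
    """Invalid configuration or parameter choice."""


class DataError(SproutspecError):
    """Invalid or degenerate input data."""


class FormatError(DataError):
    """A file does not conform to the expected dialect."""


class ParseError(DataError):
    """A value inside an otherwise well-formed file could not be parsed."""


class DuplicateWavelengthError(DataError):
    """Two columns map to the same wavelength."""


class EmptyWindowError(DataError):
    """A wavelength window does not intersect the grid."""


class MetadataConflictError(DataError):
    """Rows being merged disagree on metadata that must be constant."""


class DegenerateSpectrumError(DataError):
    """A spectrum has zero variance where variance is required."""


class DegenerateBandError(DataError):
    """A wavelength band has zero variance across samples."""


class DegenerateResponseError(DataError):
    """The regression response has zero variance."""


class FoldDesignError(DataError):
    """A cross-validation fold is missing a class or a group."""


class NegativeTitreError(DataError):
    """Sample titre below blank titre."""
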