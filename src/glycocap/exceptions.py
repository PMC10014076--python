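"""Exception hierarchy shared across the package."""


class GlycocapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GlycocapError):
    """A file violates its declared on-disk format."""


class UnsupportedVersionError(FormatError):
    """File format version outside the supported range."""


class SchemaError(GlycocapError):
    """Tabular input is missing required columns or has bad cell values."""


class LinkageError(GlycocapError):
    """A sample-sheet row references a sample that was not provided."""


class DuplicationError(GlycocapError):
    """Duplicate (condition, dose) combination in a sample sheet."""


class DomainError(GlycocapError, ValueError):
    """Input values outside the mathematical domain of an operation."""


class SampleSizeError(GlycocapError):
    """Too few cells (or doses) for the requested estimator."""


class ConfigError(GlycocapError):
    """Invalid run or simulation configuration."""


class ConvergenceWarning(UserWarning):
    """An iterative fit or optimization stopped before reaching tolerance."""
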