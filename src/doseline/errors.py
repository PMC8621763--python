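"""Exception hierarchy shared across the package."""


class DoselineError(Exception):
    """Base class for all package-specific errors."""


class DomainError(DoselineError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(DoselineError, ValueError):
    """A model or run configuration violates its invariants."""


class DataError(DoselineError, ValueError):
    """Input data are structurally valid but semantically unusable."""


class FormatError(DataError):
    """An input table is malformed (missing columns, bad units, duplicates)."""
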