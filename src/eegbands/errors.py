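"""Exception hierarchy shared across the pipeline stages."""


class EegBandsError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(EegBandsError, ValueError):
    """Raised when data handed to an operation violates its preconditions."""


class ConfigurationError(EegBandsError, ValueError):
    """Raised when parameters (not data) are inconsistent or out of range."""


class ZeroEnergyError(InvalidInputError):
    """Raised when an all-zero epoch makes relative energies undefined."""


class ManifestError(EegBandsError, ValueError):
    """Raised when a cohort manifest is missing, malformed or inconsistent."""


class EdfFormatError(EegBandsError, ValueError):
    """Raised when an EDF file cannot be parsed (bad header, truncation...)."""
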