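"""Exception hierarchy shared across the package."""


class EasilungError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EasilungError):
    """Malformed input file content (bad base, ref==alt row, ...)."""


class SchemaError(EasilungError):
    """Input table is missing mandatory columns."""


class ContractError(EasilungError):
    """A documented precondition was violated by the caller."""


class UndefinedSpectrumError(ContractError):
    """Relative frequencies requested for a zero-substitution sample."""


class EstimationError(EasilungError):
    """Model fitting failed (separation, non-convergence, rank deficiency)."""


class ConfigurationError(EasilungError):
    """Unknown model variant or invalid configuration value."""
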