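"""Exception types shared across the pipeline."""


class EcohurdleError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EcohurdleError):
    """Invalid generator or model configuration."""


class InsufficientDataError(EcohurdleError):
    """Too few usable observations to perform an operation."""


class ValidationError(EcohurdleError):
    """Input table violates a structural contract."""
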