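"""Exception and warning types shared across the pipeline."""


class SipefError(Exception):
    """Base class for all sipef errors."""


class FormatError(SipefError):
    """A file could not be parsed in the declared on-disk dialect."""


class ValidationError(SipefError, ValueError):
    """Parsed data violate a contract (range, uniqueness, design, enum)."""


class ConfigurationError(SipefError):
    """Inconsistent analysis configuration (e.g. overlapping pool windows)."""


class DesignWarning(UserWarning):
    """A replicate cell of the factorial design is incomplete."""


class DataLossWarning(UserWarning):
    """Samples or observations were dropped (under-depth, missing pool, ...)."""
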