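"""Exception types shared across the pipeline."""


class PascdxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PascdxError, ValueError):
    """A configuration value is invalid or inconsistent."""


class InsufficientDataError(PascdxError, ValueError):
    """An operation received too little data to be defined."""
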