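"""Exception hierarchy shared across the package."""


class PtewError(Exception):
    """Base class for all package errors."""


class SchemaError(PtewError, ValueError):
    """A tabular input is missing required columns or is malformed."""


class ValidationError(PtewError, ValueError):
    """A record violates a domain invariant (e.g. negative concentration)."""


class ConfigError(PtewError, ValueError):
    """A standards/exposure/distribution configuration is inconsistent."""


class NoDataError(PtewError, ValueError):
    """An operation was asked to summarise or test an empty subset."""


class PipelineError(PtewError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
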