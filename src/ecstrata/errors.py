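"""Exception hierarchy shared across the package."""


class EcstrataError(Exception):
    """Base class for all package errors."""


class FormatError(EcstrataError):
    """A file does not conform to its declared on-disk format."""


class ConsistencyError(EcstrataError):
    """Inputs are individually well formed but mutually inconsistent."""


class SchemaError(EcstrataError):
    """A table is missing required columns or has untypable cells."""


class ValidationError(EcstrataError):
    """An argument violates a documented precondition."""


class ConfigError(EcstrataError):
    """A configuration object is internally inconsistent."""


class GenerationError(EcstrataError):
    """A synthetic-data generator could not satisfy its constraints."""


class MatchingError(EcstrataError):
    """Too few eligible control genes for a matched randomization."""


class EmptyOutputError(EcstrataError):
    """A filter removed every gene or every cell."""
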