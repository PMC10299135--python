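"""Exception types shared across the package."""


class KpermeateError(Exception):
    """Base class for all package errors."""


class FormatError(KpermeateError, ValueError):
    """A file could not be parsed as the expected format."""


class ConfigurationError(KpermeateError, ValueError):
    """Invalid configuration: bad selector, missing atoms, unknown keys."""


class DomainError(KpermeateError, ValueError):
    """An argument lies outside the mathematically valid domain."""


class ParticleLookupError(KpermeateError, KeyError):
    """A particle id is not present in the trajectory."""
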