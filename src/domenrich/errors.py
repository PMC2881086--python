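"""Exception types shared across the package."""


class DomenrichError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DomenrichError):
    """A column specification, simulation spec or run configuration is invalid."""


class InputError(DomenrichError):
    """User-supplied data (tables, value lists, criteria) is invalid."""
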