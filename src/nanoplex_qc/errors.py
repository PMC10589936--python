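"""Exception hierarchy used across the package."""


class NanoplexError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NanoplexError):
    """A file does not conform to the expected dialect (bad column, bad row)."""


class ConfigError(NanoplexError):
    """A configuration value or mapping is invalid or incomplete."""


class ContractError(NanoplexError):
    """An operation was called with inputs violating its contract."""


class DataError(NanoplexError):
    """Parsed data violates a domain invariant (e.g. channel out of range)."""


class ParameterError(NanoplexError):
    """A numeric parameter is out of its valid range."""


class ValidationError(NanoplexError):
    """Cross-file consistency check failed (e.g. unknown read ids)."""
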