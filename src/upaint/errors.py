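"""Exception types shared across the pipeline stages."""


class UPaintError(Exception):
    """Base class for all package errors."""


class ConfigurationError(UPaintError):
    """A configuration value violates its documented invariant."""


class ContractError(UPaintError):
    """An operation was called with inputs that break its precondition."""


class FormatError(UPaintError):
    """An input file does not match the expected on-disk format."""
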