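"""Shared exception types."""


class GonogoError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(GonogoError, ValueError):
    """A configuration value violates a documented precondition."""


class InvalidInputError(GonogoError, ValueError):
    """Input data violate a documented precondition."""


class FormatError(GonogoError, ValueError):
    """A file is structurally unreadable or lacks required channels/fields."""


class UnsupportedOperationError(GonogoError, ValueError):
    """A requested operation is deliberately unsupported (e.g. upsampling)."""
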