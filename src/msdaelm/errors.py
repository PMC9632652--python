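"""Exception hierarchy shared across the package."""


class MsdaElmError(Exception):
    """Base class for all package errors."""


class InputError(MsdaElmError, ValueError):
    """Invalid data passed to an operation (shape, emptiness, label issues)."""


class ConfigurationError(MsdaElmError, ValueError):
    """Invalid parameter or configuration value."""


class DegenerateInputError(InputError):
    """Structurally valid input on which the operation is undefined
    (e.g. no class shared by both domains)."""
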