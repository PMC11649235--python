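"""Exception types shared across the package."""


class EthoflightError(Exception):
    """Base class for all package errors."""


class InputError(EthoflightError, ValueError):
    """An argument violates a documented precondition."""


class ConstraintError(EthoflightError, ValueError):
    """A schedule or configuration cannot satisfy its constraints."""


class FormatError(EthoflightError, ValueError):
    """A file does not conform to the expected tabular format."""
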