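"""Exception hierarchy.

``InputError`` maps to CLI exit code 2 (bad or missing input data),
``ValidationError`` to exit code 3 (an internally generated artifact failed
a structural check).
"""


class BrachyDeckError(Exception):
    """Base class for all package errors."""


class InputError(BrachyDeckError):
    """Unreadable, inconsistent or unsupported input data."""


class ValidationError(BrachyDeckError):
    """A generated artifact failed validation."""
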