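"""Exception hierarchy."""


class CocinError(Exception):
    """Base class for all package errors."""


class ParseError(CocinError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(CocinError):
    """An argument or data structure violates a documented invariant."""
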