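"""Exception hierarchy."""


class MethaploError(Exception):
    """Base class for all package errors."""


class ParseError(MethaploError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(MethaploError):
    """An in-memory object violates a documented invariant."""
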