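"""Exception hierarchy for the tici package."""


class TiciError(Exception):
    """Base class for all tici errors."""


class FormatError(TiciError):
    """A file does not conform to one of the tabular interchange formats."""


class ValidationError(TiciError):
    """Input data violate a structural invariant (duplicate samples, bad roles, ...)."""
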