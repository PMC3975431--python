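"""Exception hierarchy for dtipred."""


class DtipredError(Exception):
    """Base class for all package errors."""


class FormatError(DtipredError):
    """A file does not conform to the expected external format."""


class ValidationError(DtipredError):
    """An in-memory object violates a domain invariant or precondition."""


class UnknownIDError(DtipredError, KeyError):
    """A referenced drug or protein identifier cannot be resolved."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return DtipredError.__str__(self)
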