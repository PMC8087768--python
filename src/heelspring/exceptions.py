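"""Exception hierarchy for the pipeline."""


class HeelspringError(Exception):
    """Base class for all package errors."""


class FormatError(HeelspringError):
    """A delimited-text trial/result file violates the on-disk contract."""


class ValidationError(HeelspringError):
    """A domain object violates one of its invariants."""


class UndefinedResultError(HeelspringError):
    """A quantity is mathematically undefined for the given inputs
    (e.g. SNW of a step with zero total work, or a zero force impulse
    in the external-moment-arm ratio)."""
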