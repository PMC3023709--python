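"""Exception hierarchy shared across the toolkit."""


class ProtfunError(Exception):
    """Base class for all toolkit errors."""


class FormatError(ProtfunError):
    """An input file violates its declared format."""


class ValidationError(ProtfunError):
    """Parsed data violates a domain invariant (e.g. category out of range)."""


class AmbiguousMappingError(ValidationError):
    """An identifier maps to more than one target identifier."""


class DegenerateInputError(ProtfunError):
    """An operation received an input it is mathematically undefined on
    (empty translated sequence, zero-norm vector, ...)."""


class MissingAnnotationError(ProtfunError):
    """A residue-annotation-backed property alphabet was requested for a
    record that carries no such annotation and no fallback was enabled."""


class UnpredictableError(ProtfunError):
    """A query protein is resolvable by neither prediction method."""
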