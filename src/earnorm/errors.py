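"""Exception hierarchy shared across the toolkit."""


class EarnormError(Exception):
    """Base class for all earnorm errors."""


class FormatError(EarnormError):
    """A file could not be parsed (malformed header, wrong columns...)."""


class ValidationError(EarnormError):
    """Input parsed but violates a structural invariant."""


class InsufficientDataError(EarnormError):
    """Too few points/samples/genes for the requested computation."""


class DomainError(EarnormError, ValueError):
    """A numeric argument is outside the mathematical domain of the operation."""
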