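"""Exception hierarchy shared across the package."""


class HerbQCError(Exception):
    """Base class for all package errors."""


class FormatError(HerbQCError):
    """A file is structurally malformed (missing columns, bad header)."""


class ValidationError(HerbQCError):
    """A value violates a domain invariant (non-positive area, bad config)."""


class DomainError(ValidationError):
    """A numeric argument is outside the mathematical domain of an operation."""


class InsufficientDataError(HerbQCError):
    """Too few observations for the requested statistic."""


class AmbiguityError(HerbQCError):
    """Peak matching found more than one candidate where exactly one is required."""


class ConsistencyError(HerbQCError):
    """Parallel inputs disagree on labels (components, batches, markers)."""
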