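"""Exception hierarchy.

All package-raised errors derive from :class:`MBGraphError` so callers
(including the CLI) can distinguish validation problems from genuine bugs.
"""


class MBGraphError(Exception):
    """Base class for all errors raised by mbgraph."""


class ValidationError(MBGraphError):
    """Input violates a documented precondition or invariant."""


class ParseError(ValidationError):
    """A table cell or file fragment could not be interpreted."""


class FormatError(ValidationError):
    """A file is not in the expected on-disk format/dialect."""


class IdentifierCollisionError(ValidationError):
    """Duplicate sample or taxon identifiers."""


class UnknownIdentifierError(ValidationError):
    """An identifier refers to no known sample/taxon/node."""


class EmptyInputError(ValidationError):
    """An input table or graph contains no data."""


class DegenerateInputError(ValidationError):
    """Input is structurally valid but degenerate for the operation
    (e.g. an all-zero count vector, a single-sample distance matrix)."""


class CardinalityError(ValidationError):
    """Too many distinct categories for the requested encoding."""


class CoverageError(ValidationError):
    """A per-node map (positions, colors) does not cover every node."""


class RangeError(ValidationError):
    """An index range is empty, inverted, or out of bounds."""
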