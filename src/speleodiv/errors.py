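"""Typed errors raised by validation and parsing.

Every malformed input named in the data contracts raises one of these;
nothing is silently coerced.
"""


class SpeleodivError(Exception):
    """Base class for all package errors."""


class FormatError(SpeleodivError):
    """A file or table violates the expected format (duplicates, bad cells...)."""


class ValidationError(SpeleodivError):
    """A domain object violates one of its invariants."""


class ReferenceError_(SpeleodivError):
    """A record references an unknown unit or species id."""


class DegenerateInputError(SpeleodivError):
    """An analysis was asked of an input on which it is undefined
    (e.g. Jaccard of two empty communities)."""
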