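"""Package-level exception hierarchy.

Every stage raises a subclass of :class:`SemisolidError` so callers (and the
CLI) can distinguish bad input from numerical failure without string matching.
"""


class SemisolidError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(SemisolidError, ValueError):
    """A measurement table or parameter violates a stated precondition."""


class InsufficientDataError(SemisolidError, ValueError):
    """Too few points/replicates to perform the requested fit or test."""


class SegmentationError(SemisolidError, ValueError):
    """A texture trace does not contain the expected two-episode structure."""


class SchemaError(SemisolidError, ValueError):
    """A delimited input file is missing required columns or metadata."""
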