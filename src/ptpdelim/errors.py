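"""Exception hierarchy for ptpdelim.

All package-specific failures derive from :class:`PTPError` so callers (and the
CLI) can distinguish input/validation problems from genuine bugs.
"""


class PTPError(Exception):
    """Base class for all ptpdelim errors."""


class NewickParseError(PTPError):
    """Malformed Newick input. ``offset`` is the 0-based character column."""

    def __init__(self, message: str, offset: int | None = None, line: int | None = None):
        self.offset = offset
        self.line = line
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)


class TreeValidationError(PTPError):
    """Structurally valid Newick that violates a tree invariant
    (duplicate leaf labels, negative or missing branch lengths, ...)."""


class DegenerateDelimitationError(PTPError):
    """A delimitation with an empty among- or within-species edge class was
    given to an operation that needs both classes."""


class RateOverflowError(PTPError):
    """A branch-length class sums to zero even after the epsilon floor, so the
    exponential rate estimate would be infinite."""


class CapExceededError(PTPError):
    """Exhaustive enumeration refused: the delimitation count exceeds the cap."""

    def __init__(self, count: int, cap: int):
        self.count = count
        self.cap = cap
        super().__init__(
            f"tree admits {count} delimitations, exceeding the enumeration cap "
            f"of {cap}; use the greedy search instead"
        )


class PartitionMismatchError(PTPError):
    """Two partitions compared by NMI are not defined on the same item set."""
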