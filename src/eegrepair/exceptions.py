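"""Exception hierarchy for eegrepair."""


class EegRepairError(Exception):
    """Base class for all package errors."""


class InvalidRankError(EegRepairError, ValueError):
    """Requested factorization rank exceeds the matrix dimensions."""


class InfeasibleBlockError(EegRepairError):
    """A block violates the completability assumption: some rows or
    columns contain no observed entry, so no information constrains them.

    Attributes
    ----------
    rows, cols : list of int
        Indices of the all-missing rows / columns.
    """

    def __init__(self, rows, cols, block_index=None):
        self.rows = list(rows)
        self.cols = list(cols)
        self.block_index = block_index
        where = f" (block {block_index})" if block_index is not None else ""
        super().__init__(
            f"block not completable{where}: all-missing rows {self.rows}, "
            f"all-missing columns {self.cols}"
        )


class SingularSystemError(EegRepairError):
    """The least-squares system for the core matrix is rank deficient
    (too few observed entries for the requested rank)."""

    def __init__(self, msg, block_index=None):
        self.block_index = block_index
        if block_index is not None:
            msg = f"{msg} (block {block_index})"
        super().__init__(msg)


class DataError(EegRepairError, ValueError):
    """Input data violates a basic requirement (e.g. non-finite values)."""
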