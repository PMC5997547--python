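"""Exception hierarchy for bctseg.

Distinct error classes separate I/O and format problems (bad files,
inconsistent slice shapes) from algorithmic failures (no skin contour,
unimodal histogram), so the pipeline and the CLI can react differently
to each: format errors abort, per-slice segmentation errors are logged
and the slice is skipped.
"""


class BctsegError(Exception):
    """Base class for all bctseg errors."""


class FormatError(BctsegError):
    """Unreadable or internally inconsistent input file(s)."""


class SpecError(BctsegError):
    """Invalid phantom specification (geometry cannot be realized)."""


class SegmentationError(BctsegError):
    """A segmentation stage failed on this slice (e.g. no closed contour)."""


class DegenerateInputError(BctsegError):
    """Input violates a statistical precondition (constant image,
    unimodal histogram, empty foreground)."""


class NonConvergenceError(BctsegError):
    """Iterative stage hit its iteration cap; carries the best state."""

    def __init__(self, message, best_state=None):
        super().__init__(message)
        self.best_state = best_state


class UndefinedMetricError(BctsegError):
    """A similarity metric is undefined for the given masks."""


class ConsistencyError(BctsegError):
    """Masks that must be disjoint/partitioning are not."""
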