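"""Exception hierarchy.

All package errors derive from :class:`CodacError` so callers can catch
pipeline failures without masking programming errors.
"""


class CodacError(Exception):
    """Base class for all codac errors."""


class ValidationError(CodacError):
    """Invalid input data or configuration (bad identifiers, paths, shapes)."""


class ShuffleInfeasibleError(CodacError):
    """No degree-preserving, non-overlapping edge rearrangement was found.

    Raised both when such a rearrangement provably does not exist (e.g. a
    complete bipartite graph, where every degree-preserving graph equals the
    original) and when the retry budget is exhausted without finding one.
    """


class DegenerateCalibrationError(CodacError):
    """Calibration cannot proceed (no positives, no scored candidates, ...)."""
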