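"""Exception hierarchy for graftvol."""


class GraftVolError(Exception):
    """Base class for all graftvol errors."""


class InvalidSpecError(GraftVolError):
    """A phantom specification is geometrically impossible (non-positive
    dimension, overlapping implant and defect, ...)."""


class ResolutionError(GraftVolError):
    """The requested voxel spacing is too coarse to resolve the geometry."""


class ConvergenceError(GraftVolError):
    """An iterative scaling did not reach its volume target.

    Carries the last achieved volume in ``achieved``.
    """

    def __init__(self, message: str, achieved: float):
        super().__init__(message)
        self.achieved = achieved


class DistortedInputError(GraftVolError):
    """Sparse annotations leave a gap larger than ``max_gap`` slices, so the
    interpolation premise (a usable slice within the gap window) is violated."""


class UndefinedStatisticError(GraftVolError):
    """A statistic is requested from too few values (e.g. CV of one repeat)."""


class EmptyMaskError(GraftVolError):
    """A surface was requested from an empty mask."""


class DegenerateLandmarksError(GraftVolError):
    """Landmark configuration is collinear or too small for a rigid fit."""
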