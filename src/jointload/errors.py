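"""Exception hierarchy for the pipeline."""


class JointloadError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(JointloadError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateGeometryError(JointloadError):
    """Requested geometry cannot be represented on the voxel grid."""


class SegmentationError(JointloadError):
    """Thresholding produced no foreground."""


class FitError(JointloadError):
    """A geometric fit (plane, circle, arc) failed or is degenerate."""


class LoadAreaError(JointloadError):
    """No cartilage surface nodes fall inside the requested load area."""


class SolverError(JointloadError):
    """The linear solver failed to converge or the system is singular."""


class EmptyMaskError(JointloadError):
    """The trabecular mask is empty; the inverse problem is undefined."""


class UndefinedMetricError(JointloadError):
    """A metric (CoV, direction) is undefined for the given input."""
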