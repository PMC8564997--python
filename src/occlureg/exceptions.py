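"""Typed errors raised across the pipeline.

Degenerate inputs (collinear landmarks, coplanar sphere samples, constant
statistic matrices) raise these instead of silently returning NaN.
"""


class OccluregError(Exception):
    """Base class for all package errors."""


class InvalidLayoutError(OccluregError, ValueError):
    """Plate layout violates its invariants (bad radius, duplicate IDs...)."""


class InvalidLabelError(OccluregError, KeyError):
    """A concave label outside the 18 valid FDI-style tokens."""


class DegenerateFrameError(OccluregError, ValueError):
    """Observation-frame landmarks are collinear or missing."""


class InvalidTransformError(OccluregError, ValueError):
    """A claimed rotation matrix is not proper orthogonal."""


class DegenerateFitError(OccluregError, ValueError):
    """Sphere fit is underdetermined (too few or coplanar points)."""


class SphereFitNumericalError(OccluregError, ArithmeticError):
    """Non-finite objective during geometric sphere refinement."""


class InsufficientLandmarksError(OccluregError, ValueError):
    """Fewer than three correspondences given to a rigid alignment."""


class DegenerateConfigurationError(OccluregError, ValueError):
    """Registration landmarks are collinear; the optimum is not unique."""


class UndefinedStatisticError(OccluregError, ValueError):
    """A statistic's defining mean squares are all zero (constant data)."""
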