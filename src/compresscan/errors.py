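"""Exception hierarchy shared across the package."""


class CompresscanError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CompresscanError, ValueError):
    """Malformed or degenerate input data (bad record, empty list, ...)."""


class InvalidGeometryError(CompresscanError, ValueError):
    """Geometric preconditions violated (non-positive radius, a >= b, ...)."""


class InvalidTissueError(CompresscanError, ValueError):
    """Tissue constitutive parameters out of their physical range."""


class EmptyContourError(CompresscanError, ValueError):
    """No marker pixels found in an image."""


class NonStarShapedError(CompresscanError, ValueError):
    """Centroid lies outside the contour polygon."""


class InvalidPairingError(CompresscanError, ValueError):
    """Two profiles cannot be differenced (grid or identity mismatch)."""


class InvalidSpecError(CompresscanError, ValueError):
    """A synthetic-data specification violates its invariants."""

class InvalidFieldError(CompresscanError, ValueError):
    """A deformation field would produce non-positive radii."""


class IntegrationError(CompresscanError, ValueError):
    """The dynamic integrator hit non-finite forcing or state."""


class StageError(CompresscanError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
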