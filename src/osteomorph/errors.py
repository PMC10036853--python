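"""Exception hierarchy shared by all osteomorph stages."""


class OsteomorphError(Exception):
    """Base class for all osteomorph errors."""


class SpecValidationError(OsteomorphError, ValueError):
    """A synthetic-bone or pipeline spec violates its invariants."""

    def __init__(self, message: str, fields: list[str] | None = None):
        self.fields = list(fields or [])
        super().__init__(message)


class MeshIOError(OsteomorphError, IOError):
    """A mesh file could not be parsed or written."""


class DegenerateGeometryError(OsteomorphError, ValueError):
    """Input points do not constrain the requested primitive (coplanar,
    near-spherical, insufficient extent, ...)."""


class ConvergenceError(OsteomorphError, RuntimeError):
    """An iterative fit failed to converge; carries the residual trace."""

    def __init__(self, message: str, residuals: list[float] | None = None):
        self.residuals = list(residuals or [])
        super().__init__(message)


class ConditioningError(OsteomorphError, RuntimeError):
    """A linear system (e.g. an RBF interpolation with duplicate control
    points) is singular or numerically unusable."""


class QualityGateError(OsteomorphError, RuntimeError):
    """A stage result failed its configured quality bound (e.g. final
    correspondence RMS above the ceiling, or a patch fit with excessive
    residual indicating a bone-type mismatch)."""


class MissingLandmarkError(OsteomorphError, KeyError):
    """A measurement requires a landmark that is absent from the set."""


class ResolutionError(OsteomorphError, ValueError):
    """Polygonization resolution too coarse to produce a usable surface."""
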