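"""Exception hierarchy for perifem."""


class PerifemError(Exception):
    """Base class for all perifem errors."""


class SizingError(PerifemError):
    """Domain too small to hold the requested shell, interior or implants."""


class GenerationError(PerifemError):
    """Synthetic specimen could not reach the requested morphometry."""

    def __init__(self, msg: str, achieved: float | None = None):
        super().__init__(msg)
        self.achieved = achieved


class GeometryError(PerifemError):
    """An implant (or other solid) extends outside the voxel domain."""


class ResamplingError(PerifemError):
    """Requested output spacing is not an integer multiple of the source."""


class DegenerateImageError(PerifemError):
    """Image has too few distinct intensities for discriminant analysis."""


class SeedingError(PerifemError):
    """Graph-cut seeds missing for a required class, or inconsistent."""


class ModelError(PerifemError):
    """Label map cannot be turned into a solvable mesh."""


class InterfaceError(PerifemError):
    """No implant-bone interface exists in the mesh."""


class LoadingError(PerifemError):
    """Load node set is empty or conflicts with fixed nodes."""


class MaterialError(PerifemError):
    """Material table does not cover a label present in the mesh."""


class RigidModeError(PerifemError):
    """A connected component of the mesh has no constrained node."""


class ConvergenceError(PerifemError):
    """Iterative solver failed to reach the requested residual."""

    def __init__(self, msg: str, report=None):
        super().__init__(msg)
        self.report = report
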