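"""Exception hierarchy shared across the package."""


class HalopathError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(HalopathError):
    """A geometric quantity is undefined for the given atoms (coincident points, etc.)."""


class SurfaceConstructionError(HalopathError):
    """An analytic energy surface could not be built from the given parameters."""


class IntegrationError(HalopathError):
    """Stochastic propagation produced a non-finite configuration."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite state encountered at step {step}")


class AdiabaticMapError(HalopathError):
    """Constrained minimization failed at a reaction-coordinate grid point."""

    def __init__(self, grid_index: int, rc_value: float, detail: str = ""):
        self.grid_index = grid_index
        self.rc_value = rc_value
        msg = f"minimization did not converge at grid point {grid_index} (rc = {rc_value:g})"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class EstimatorError(HalopathError):
    """A free-energy estimator could not produce a result."""


class BarConvergenceError(EstimatorError):
    """Bennett self-consistent solution did not converge; carries the last iterate."""

    def __init__(self, last_iterate: float, message: str | None = None):
        self.last_iterate = last_iterate
        super().__init__(message or f"BAR did not converge (last iterate {last_iterate:g})")


class NoTransitionStateError(HalopathError):
    """A profile has no interior maximum between two basins."""


class XYZParseError(HalopathError):
    """Malformed multi-frame XYZ input; carries the offending line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class ConfigError(HalopathError):
    """Invalid or inconsistent pipeline configuration."""


class PipelineStageError(HalopathError):
    """A pipeline stage failed; wraps the original error with the stage name."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
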