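"""Named error classes raised across the pipeline.

Each failure mode the loaders and stages can hit gets its own class so
callers (and the CLI) can report precisely what went wrong.
"""


class RsgicaError(Exception):
    """Base class for all package errors."""


class MissingInputError(RsgicaError):
    """A file named in a manifest or required by a stage does not exist."""


class GridMismatchError(RsgicaError):
    """Two volumes/masks that must share a voxel grid do not."""


class MotionLengthMismatchError(RsgicaError):
    """Motion trace row count differs from the run's volume count."""


class InvalidVolumeError(RsgicaError):
    """A volume violates a basic invariant (NaN values, empty time axis...)."""


class BandError(RsgicaError):
    """A requested frequency band is infeasible for the sampling rate."""


class PlacementError(RsgicaError):
    """Phantom source placement could not satisfy the overlap constraint."""


class ConvergenceError(RsgicaError):
    """No ICA restart converged; carries per-restart diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class StageDependencyError(RsgicaError):
    """A pipeline stage was invoked before the stage it depends on."""
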