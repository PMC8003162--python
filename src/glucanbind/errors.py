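"""Exception hierarchy for glucanbind."""


class GlucanBindError(Exception):
    """Base class for all package errors."""


class PackingError(GlucanBindError):
    """Raised when ligands cannot be placed with the required receptor standoff."""


class TimestepError(GlucanBindError):
    """Raised when a Brownian step exceeds the per-step displacement bound."""


class TrajectoryFormatError(GlucanBindError):
    """Malformed trajectory file; carries the offending frame index."""

    def __init__(self, message, frame_index=None):
        super().__init__(message)
        self.frame_index = frame_index


class SelectionError(GlucanBindError):
    """A selection query resolves to an empty or invalid particle set."""


class AlignmentError(GlucanBindError):
    """Rigid-body superposition is underdetermined (too few / collinear points)."""


class DensityError(GlucanBindError):
    """Invalid density-map request (empty selection, zero frames, bad threshold)."""


class AmbientConcentrationError(DensityError):
    """Ambient concentration cannot be estimated (too few far-field voxels, or zero)."""


class StrideError(GlucanBindError):
    """Time series has a non-uniform stride; resample before event detection."""


class EventConsistencyError(GlucanBindError):
    """Binding events overlap or are otherwise internally inconsistent."""


class GridMismatchError(GlucanBindError):
    """Mean-force grids with different coordinate specifications cannot combine."""


class TruncationError(GlucanBindError):
    """Quadrature domain truncates a non-negligible part of the integrand."""


class GaugeError(GlucanBindError):
    """Separation PMF is not gauged to zero at the bulk reference separation."""


class ConfigError(GlucanBindError):
    """Invalid pipeline configuration (unknown key, missing parameter)."""
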