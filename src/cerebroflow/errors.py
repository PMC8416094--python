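"""Exception hierarchy shared across the package."""


class CerebroflowError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(CerebroflowError):
    """Nonpositive or otherwise impossible vessel geometry."""


class ConvergenceError(CerebroflowError):
    """A solver or calibration loop failed to converge.

    Carries a ``trace`` attribute with per-iteration diagnostics when available.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class DegenerateSignalError(CerebroflowError):
    """Signal carries no usable information (flat waveform, zero integral)."""


class FormatError(CerebroflowError):
    """Malformed input file or inconsistent metadata."""


class GridMismatchError(FormatError):
    """Image grids that must coincide do not."""


class StructuralError(CerebroflowError):
    """Network topology violates a structural requirement."""


class InconsistentMeasurementsError(CerebroflowError):
    """Measurements are mutually incompatible (e.g. branch flows exceed inflow)."""
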