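"""Exception hierarchy shared across the package.

Every error that reports geometry carries the offending shapes in its message,
using 0-based, half-open, row-major coordinates throughout.
"""


class P3DStageError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(P3DStageError, ValueError):
    """A scalar argument violates a documented precondition."""


class ShapeError(P3DStageError, ValueError):
    """Tensor shape contract violation; message reports both shapes."""


class GeometryError(P3DStageError, ValueError):
    """Crop box / frame geometry violation."""


class WindowError(P3DStageError, ValueError):
    """Not enough frames remain to take the requested temporal window."""


class ConfigError(P3DStageError, ValueError):
    """Invalid network or run configuration."""


class DataError(P3DStageError, ValueError):
    """Dataset violates a training precondition (e.g. a class is missing)."""


class DivergenceError(P3DStageError, RuntimeError):
    """Training produced a non-finite loss; names the epoch."""


class UndefinedMetricError(P3DStageError, ValueError):
    """A metric is undefined for the given inputs (e.g. no positive samples)."""


class DemoGateError(P3DStageError, RuntimeError):
    """The end-to-end demo failed one of its quality gates."""

    def __init__(self, message, record=None):
        super().__init__(message)
        self.record = record
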