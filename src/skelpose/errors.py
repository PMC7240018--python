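"""Exception hierarchy shared across the pipeline."""


class SkelposeError(Exception):
    """Base class for user-facing errors (bad input, bad configuration)."""


class ConfigurationError(SkelposeError):
    """Invalid parameter or selection-spec value."""


class CalibrationError(SkelposeError):
    """Camera calibration is missing or not a proper rigid transform."""


class FormatError(SkelposeError):
    """A frame/feature file violates the documented format contract."""


class DegenerateGeometryError(SkelposeError):
    """A body segment has (near-)zero length; the angle is undefined."""


class ConvergenceError(RuntimeError):
    """Training failed to converge; carries the last model state."""

    def __init__(self, message, model=None):
        super().__init__(message)
        self.model = model
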