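"""Exception hierarchy for dtims."""


class DtimsError(Exception):
    """Base class for all dtims errors."""


class ParameterError(DtimsError, ValueError):
    """A physical or numerical parameter is out of its valid domain."""


class GridError(DtimsError, ValueError):
    """Grid construction failed (e.g. dx does not divide the drift length)."""


class CourantError(DtimsError, ValueError):
    """The advection step was requested at a Courant number other than 1."""


class TruncatedPeakError(DtimsError, ValueError):
    """A spectrum ends before the peak (or its flanks) is fully recorded."""


class NoDipError(DtimsError, ValueError):
    """An inverse spectrum has no strict interior minimum to baseline on."""


class AxisMismatchError(DtimsError, ValueError):
    """Two spectra were combined without sharing a common time axis."""


class SpectrumParseError(DtimsError, ValueError):
    """A spectrum file could not be parsed; carries the offending line."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ScenarioError(DtimsError, ValueError):
    """A scenario configuration file is missing keys or fails validation."""
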