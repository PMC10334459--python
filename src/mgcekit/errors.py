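"""Exception hierarchy shared across the toolbox."""


class MGCEError(Exception):
    """Base class for all toolbox errors."""


class ParseError(MGCEError):
    """A landmark/report file could not be parsed; message names the line."""


class SchemaError(MGCEError):
    """Input violates a documented schema (wrong point count, bad field)."""


class GeometryError(MGCEError):
    """Degenerate or invalid geometry (zero-area box, non-finite point)."""


class InputError(MGCEError):
    """Required input missing or malformed."""


class ParameterError(MGCEError):
    """A parameter is outside its valid range for the given data."""


class InsufficientDataError(MGCEError):
    """Too few usable frames/samples for the requested analysis."""


class DetectionError(MGCEError):
    """An event the analysis requires (e.g. a stand-up rise) was not found."""


class FitError(MGCEError):
    """A model fit could not be performed (e.g. zero variance in time)."""


class MeasurementUnavailable(MGCEError):
    """Geometry quality is too low for the requested measurement."""


class GradingUnavailable(MGCEError):
    """An exam item cannot be graded; message states the missing input."""


class ValidationError(MGCEError):
    """Inputs are mutually inconsistent (e.g. onset beyond exercise end)."""
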