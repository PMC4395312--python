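"""Exception hierarchy."""


class MotorPoolError(Exception):
    """Base class for all package errors."""


class ParameterError(MotorPoolError, ValueError):
    """Invalid simulation or analysis parameter."""


class GeometryError(MotorPoolError, ValueError):
    """Degenerate or inconsistent section geometry."""


class InsufficientDataError(MotorPoolError, ValueError):
    """Too few observations for the requested statistic."""


class TraceFormatError(MotorPoolError, ValueError):
    """Trace CSV file violates the documented dialect."""
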