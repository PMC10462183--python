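"""Exception types shared across the pipeline."""


class GlycoscopeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(GlycoscopeError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateGeometryError(GlycoscopeError, ArithmeticError):
    """The optical geometry is pathological (e.g. grazing incidence, zero admittance)."""


class CalibrationError(GlycoscopeError, ValueError):
    """A FLIM calibration reference is unusable (e.g. zero modulation)."""


class EmptyROIError(GlycoscopeError, ValueError):
    """A requested subregion contains no usable pixels."""


class FormatError(GlycoscopeError, ValueError):
    """An input file does not match the expected on-disk layout."""
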