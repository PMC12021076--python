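"""Exception hierarchy for axonquant."""


class AxonQuantError(Exception):
    """Base class for package errors."""


class ConfigurationError(AxonQuantError, ValueError):
    """Invalid simulation or analysis configuration."""


class GeometryError(AxonQuantError, ValueError):
    """Nerve geometry inconsistent with the data (e.g. crush plane off-image)."""


class ResourceError(AxonQuantError, RuntimeError):
    """A requested computation exceeds a configured size cap."""


class DegenerateInputError(AxonQuantError, ValueError):
    """Input carries no usable signal (constant image, empty field, ...)."""


class InsufficientLengthError(AxonQuantError, ValueError):
    """An axon is too short for the requested measurement windows."""


class UndefinedRatioError(AxonQuantError, ZeroDivisionError):
    """A ratio with a zero denominator (e.g. no control cells)."""


class SampleSizeError(AxonQuantError, ValueError):
    """Too few observations for the requested statistical test."""
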