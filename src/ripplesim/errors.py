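"""Exception types shared across the package."""


class RippleSimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RippleSimError, ValueError):
    """A parameter value is outside its documented domain."""


class ShapeError(RippleSimError, ValueError):
    """A waveform or histogram does not have the shape an operation requires."""


class GeometryError(RippleSimError, ValueError):
    """Cell/electrode layout violates a geometric requirement."""


class SchedulingError(RippleSimError, ValueError):
    """A drive schedule cannot be realized (e.g. overlapping events)."""


class IntegrationError(RippleSimError, RuntimeError):
    """Numerical integration of the network diverged."""


class ConfigError(RippleSimError, ValueError):
    """A network configuration is internally inconsistent."""
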