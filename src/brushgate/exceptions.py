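"""Exception hierarchy shared across the solvers."""


class BrushgateError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(BrushgateError, ValueError):
    """A geometric precondition is violated (e.g. layer height exceeds pore radius)."""


class NumericalError(BrushgateError, RuntimeError):
    """A solver failed to converge or produced an unphysical result."""


class ConfigError(BrushgateError, ValueError):
    """A run configuration is malformed or contains unknown/invalid keys."""
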