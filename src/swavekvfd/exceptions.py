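"""Exception hierarchy shared across the package."""


class SwaveError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SwaveError, ValueError):
    """A material parameter or function argument is outside its physical domain."""


class ConfigError(SwaveError, ValueError):
    """A processing configuration value is invalid (e.g. even median kernel)."""


class ShapeError(SwaveError, ValueError):
    """Records or vectors that must agree in shape/sampling do not."""


class SchemaError(SwaveError, ValueError):
    """A delimited-text input does not match the expected column schema."""


class NoOnsetError(SwaveError, RuntimeError):
    """The knee detector found no threshold crossing (flat or empty signal)."""


class AcausalPickError(SwaveError, RuntimeError):
    """The receive-channel onset was picked at or before the transmit onset."""


class FitError(SwaveError, RuntimeError):
    """All optimizer starts failed to converge."""
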