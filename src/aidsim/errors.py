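"""Exception types shared across the package."""


class AidsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(AidsimError, ValueError):
    """An argument violates a documented precondition."""


class ConfigError(AidsimError, ValueError):
    """A scenario or controller configuration is malformed."""


class IntegrationError(AidsimError, RuntimeError):
    """The ODE integrator produced a non-finite state."""


class GlucoseExcursionError(AidsimError, RuntimeError):
    """Blood glucose exceeded the configured sanity ceiling.

    This is a diagnostic guard: the virtual patient model is only
    physiologically meaningful well below this ceiling, so crossing it
    indicates a mis-configured scenario or an unstable control loop.
    """


class ManifestError(AidsimError, RuntimeError):
    """A run manifest does not match the files on disk."""
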