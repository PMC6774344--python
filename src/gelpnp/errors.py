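"""Exception hierarchy for gelpnp."""


class GelPnpError(Exception):
    """Base class for all gelpnp errors."""


class ParameterError(GelPnpError, ValueError):
    """A physical parameter lies outside its admissible domain."""


class UnsupportedConfigurationError(GelPnpError, ValueError):
    """A configuration outside the supported model class (e.g. multivalent Donnan)."""


class ValidationError(GelPnpError, ValueError):
    """A parameter set violates a type invariant.

    ``name`` identifies the violated invariant.
    """

    def __init__(self, name: str, message: str):
        self.name = name
        super().__init__(f"{name}: {message}")


class GeometryError(GelPnpError, ValueError):
    """Invalid geometry specification (e.g. gel touching the bath boundary)."""


class MeshImportError(GelPnpError, ValueError):
    """A mesh file is malformed or lacks required region/boundary tags."""


class DimensionError(GelPnpError, ValueError):
    """Array layouts do not conform to the mesh/function-space layout."""


class OptionError(GelPnpError, ValueError):
    """Invalid solver or protocol option (e.g. non-positive time step)."""


class ScalingError(GelPnpError, ValueError):
    """Nondimensionalization impossible (e.g. zero reference concentration)."""


class ConvergenceError(GelPnpError, RuntimeError):
    """Newton (or time stepping) failed to converge.

    Carries the residual-norm history of the failed solve.
    """

    def __init__(self, message: str, history=None):
        self.history = list(history) if history is not None else []
        super().__init__(message)


class ExtractionError(GelPnpError, ValueError):
    """A sampling line or point lies outside the computational domain."""


class ConfigError(GelPnpError, ValueError):
    """A run configuration file is invalid; message carries the key path."""


class MobilityInconsistencyWarning(UserWarning):
    """Stored ionic mobility disagrees with the Nernst-Einstein relation."""
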