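"""Exception hierarchy shared across the package."""


class FemremError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FemremError, ValueError):
    """A geometric or physical parameter is outside its admissible range."""


class PlacementError(FemremError):
    """No seating depth keeps the stem inside the bone."""


class MeshingError(FemremError):
    """Triangulation of the domain failed."""


class SolverError(FemremError):
    """The constrained linear system could not be solved."""


class EmptyZoneError(FemremError):
    """A Gruen zone contains no interface-band elements."""


class InsufficientDataError(FemremError):
    """Too few observations for the requested estimator."""


class ConfigError(FemremError):
    """A run configuration is malformed or incomplete."""
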