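"""Exception hierarchy shared across the pipeline stages."""


class ConnatlasError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ConnatlasError):
    """A file could not be read or written under the requested standard."""


class ConfigurationError(ConnatlasError):
    """Required metadata or parameters are missing or inconsistent."""


class ValidationError(ConnatlasError):
    """A table or hierarchy failed its structural invariants."""


class GeometryError(ConnatlasError):
    """Volume shapes or voxel geometries do not match."""


class LookupError_(ConnatlasError):
    """An id was not found in the region table."""


class BoundaryError(ConnatlasError):
    """A physical coordinate falls outside the volume."""


class CapacityError(ConnatlasError):
    """A simulation request cannot be satisfied in the given volume."""


class SimulationError(ConnatlasError):
    """A stochastic construction failed within its retry budget."""


class DataError(ConnatlasError):
    """Input data are degenerate (all-NaN, empty, ...)."""


class DegenerateProfileError(ConnatlasError):
    """Normalization impossible: no signal or somata outside the injection site."""


class InputError(ConnatlasError):
    """Operation received structurally invalid arguments."""


class DependencyError(ConnatlasError):
    """A pipeline stage is missing an upstream artifact."""
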