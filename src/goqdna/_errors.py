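"""Exception hierarchy shared across the package."""


class GoqdnaError(Exception):
    """Base class for all package errors."""


class FormatError(GoqdnaError):
    """A file could not be parsed under the requested dialect."""


class UnsupportedFormatError(GoqdnaError):
    """File format could not be determined or is not supported."""


class TopologyMismatchError(GoqdnaError):
    """Trajectory frames do not match the supplied topology."""


class SelectionError(GoqdnaError):
    """A selection expression failed to parse or resolve."""


class CapacityError(GoqdnaError):
    """More functional groups requested than edge sites available."""


class PlacementError(GoqdnaError):
    """Requested assembly geometry cannot be packed."""


class ParameterError(GoqdnaError):
    """An atom is missing a required parameter (vdW radius, LJ type, ...)."""


class ConfigError(GoqdnaError):
    """A run configuration is invalid."""
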