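"""Exception hierarchy for the adlayers package."""


class AdlayersError(Exception):
    """Base class for all package errors."""


class FormatError(AdlayersError):
    """A structure or table file could not be parsed."""


class BoxError(AdlayersError):
    """Periodic box information is missing or invalid."""


class TrajectoryError(AdlayersError):
    """Frames of a trajectory are inconsistent."""


class ValidationError(AdlayersError):
    """An input value violates a documented invariant."""


class ConfigurationError(AdlayersError):
    """An unknown table, key or option was requested."""


class TilingError(AdlayersError):
    """A lattice does not tile the requested box."""


class PackingError(AdlayersError):
    """Random placement could not satisfy the no-overlap constraint."""


class GeometryError(AdlayersError):
    """A requested geometric construction is impossible."""


class EmptySurfaceError(AdlayersError):
    """The probe found no contact anywhere on the surface."""


class SelectionError(AdlayersError):
    """An atom selector returned an empty or invalid selection."""


class BinningError(AdlayersError):
    """All separation bins are empty."""


class ClassificationError(AdlayersError):
    """Not enough information to classify (missing labels or bins)."""


class FitError(AdlayersError):
    """A least-squares fit is under-determined or rejected."""
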