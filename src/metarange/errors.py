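"""Exception hierarchy shared across the pipeline stages."""


class MetarangeError(Exception):
    """Base class for all package errors."""


class ExtentError(MetarangeError):
    """A coordinate falls outside the grid extent."""


class GeometryError(MetarangeError):
    """A species geometry is invalid, empty, or unsupported."""


class GridMismatchError(MetarangeError):
    """Layers that must share a GridSpec do not."""


class UnknownSpeciesError(MetarangeError):
    """A species id is absent from the metaweb."""


class ConfigurationError(MetarangeError):
    """Inputs are mutually inconsistent (e.g. species sets disagree)."""


class UndefinedStatisticError(MetarangeError):
    """A requested statistic has an empty denominator."""


class EmptyStudyAreaError(MetarangeError):
    """No grid cell contains any species."""


class FeasibilityError(MetarangeError):
    """A synthetic scenario cannot be realised on the requested grid."""
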