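"""Exception hierarchy.

Every failure mode the pipeline can hit deliberately has its own class so the
CLI can map them to distinct exit codes and tests can assert on them.
"""


class MaxNdviError(Exception):
    """Base class for all package errors."""


class RasterFormatError(MaxNdviError):
    """A raster file is missing required bands or metadata."""


class GridMismatchError(MaxNdviError):
    """Two rasters that must share a geogrid do not."""


class GeometryError(MaxNdviError):
    """A geometry (ROI, boundary line) is empty or outside the grid."""


class NoValidPixelsError(MaxNdviError):
    """A statistic was requested over zero valid pixels."""


class NoReferenceError(MaxNdviError):
    """Every reference candidate was rejected for a year."""


class EmptyCollectionError(MaxNdviError):
    """An operation received an empty image collection."""


class ConfigError(MaxNdviError):
    """A run or simulation configuration is malformed or infeasible."""
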