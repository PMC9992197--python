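"""Exception types shared across the pipeline."""


class CorespecError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CorespecError, ValueError):
    """An invalid parameter or parameter combination."""


class ShapeMismatchError(CorespecError, ValueError):
    """Array dimensions inconsistent between pipeline objects."""


class DegenerateGeometryError(CorespecError, ValueError):
    """Geometry too degenerate to process (e.g. coplanar vertex cloud)."""


class NoCleanSegmentError(CorespecError, RuntimeError):
    """No artifact-free analysis window of the requested length exists."""


class NotPositiveDefiniteError(CorespecError, ValueError):
    """A covariance matrix is not positive definite; increase shrinkage."""


class MissingDataError(CorespecError, ValueError):
    """Required cells/files are absent from an input table or directory."""
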