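"""Typed exceptions shared across the package."""


class XerosubvolError(Exception):
    """Base class for all package errors."""


class GridMismatchError(XerosubvolError):
    """Two volumes do not share the same voxel grid."""


class ValidationError(XerosubvolError):
    """An input object violates its contract."""


class SizingError(XerosubvolError):
    """The voxel grid is too small to contain a requested structure."""


class ConfigurationError(XerosubvolError):
    """A configuration value is inconsistent or names an unknown entity."""


class EmptyRegionError(XerosubvolError):
    """A derived region collapsed to zero voxels."""


class ConvergenceError(XerosubvolError):
    """An iterative solver failed to reach its tolerance."""
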