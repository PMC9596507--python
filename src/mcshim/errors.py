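"""Structured exceptions raised across the toolkit."""


class McShimError(Exception):
    """Base class for all toolkit errors."""


class ShapeMismatchError(McShimError):
    """Input grids do not have identical shapes."""


class AcquisitionError(McShimError):
    """Invalid acquisition parameters (e.g. non-positive echo spacing)."""


class EmptyMaskError(McShimError):
    """An operation requiring mask voxels received an empty mask."""


class GeometryError(McShimError):
    """A coil geometry violates its physical constraints."""


class OverlapError(GeometryError):
    """Two loop elements overlap on the former surface."""


class BasisError(McShimError):
    """A shim basis is malformed or degenerate for the requested fit."""


class SolverError(McShimError):
    """The shim solver received an infeasible or ill-posed problem."""


class ConfigError(McShimError):
    """Unknown method label or invalid configuration value."""
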