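"""Exception hierarchy shared across the package."""


class VolumetrixError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(VolumetrixError, ValueError):
    """A numeric parameter is outside its admissible range."""


class GeometryError(VolumetrixError, ValueError):
    """A geometric construction is inconsistent (overlap, self-intersection, out of bounds)."""


class ResolutionError(VolumetrixError, ValueError):
    """The sampling grid is too coarse to resolve the requested structure."""


class EmptyRoiError(VolumetrixError, ValueError):
    """A region of interest came out empty where a non-empty one is required."""
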