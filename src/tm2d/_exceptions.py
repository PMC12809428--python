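"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument is outside its documented range or otherwise invalid."""


class GeometryError(ValueError):
    """A geometric operation received degenerate input (collinear points, ...)."""


class PixelSizeMismatchError(ValueError):
    """Template and micrograph pixel sizes disagree beyond tolerance."""


class MrcFormatError(IOError):
    """An MRC file could not be parsed or uses an unsupported feature."""
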