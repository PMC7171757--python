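"""Exception hierarchy shared across the pipeline."""


class RadsurvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RadsurvError):
    """Invalid configuration or parameter value; raised before any compute."""


class GeometryError(RadsurvError):
    """Volume/mask shape or spacing inconsistency."""


class EmptyRoiError(RadsurvError):
    """A mask with no foreground voxels was passed where an ROI is required."""
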