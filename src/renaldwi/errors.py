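"""Exception types shared across the pipeline."""


class RenalDwiError(ValueError):
    """Base class for contract violations in this package."""


class ProtocolError(RenalDwiError):
    """Unknown protocol name or a protocol unsuitable for the requested model."""


class FitError(RenalDwiError):
    """A voxel-wise or ROI-level fit cannot be performed on the given input."""


class ConfigError(RenalDwiError):
    """Invalid or incomplete run configuration."""


class GridMismatchError(RenalDwiError):
    """Two gridded objects (image / mask / mesh) do not share a grid."""
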