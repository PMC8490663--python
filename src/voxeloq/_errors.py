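"""Exception hierarchy shared across the package."""


class VoxeloqError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(VoxeloqError):
    """Raised when a volume's affine or grid geometry is invalid or mismatched."""


class DimensionalityError(VoxeloqError):
    """Raised when an image is not a 3-D volume."""


class ConfigurationError(VoxeloqError):
    """Raised when a panel, label table, or config references something undefined."""


class CapacityError(VoxeloqError):
    """Raised when an exact enumeration would exceed its table-count guard."""


class UndefinedStatisticError(VoxeloqError):
    """Raised when a statistic is undefined for the given input (e.g. pe = 1)."""
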