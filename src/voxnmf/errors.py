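"""Exception hierarchy shared across the package."""


class VoxnmfError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(VoxnmfError):
    """Array shapes, affines, or column layouts do not conform."""


class DataError(VoxnmfError):
    """Input values are invalid (NaN/Inf in masked regions, misaligned IDs)."""


class DomainError(VoxnmfError):
    """Values violate a domain constraint (e.g. negative intensities)."""


class ArgumentError(VoxnmfError):
    """An argument is out of its allowed range."""


class NormalizationError(VoxnmfError):
    """Reference-region normalization is impossible (non-positive median)."""


class NumericalError(VoxnmfError):
    """The optimizer produced a non-finite quantity."""


class InsufficientDataError(VoxnmfError):
    """Too few complete cases to fit a model."""


class DegenerateOutcomeError(VoxnmfError):
    """The response has no variance or a class with too few members."""


class GenerationError(VoxnmfError):
    """A synthetic-data constraint could not be satisfied."""


class StageError(VoxnmfError):
    """A pipeline stage prerequisite is missing."""
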