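"""Exception hierarchy shared across the pipeline stages."""


class HurstFmriError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HurstFmriError, ValueError):
    """A parameter is outside its admissible range."""


class InvalidInputError(HurstFmriError, ValueError):
    """An input array/table violates a precondition (shape, length, rank)."""


class DegenerateInputError(HurstFmriError, ValueError):
    """Input is degenerate for the requested statistic (e.g. constant series)."""


class DegenerateFeatureError(DegenerateInputError):
    """Both groups of a feature are constant: Fisher score undefined."""


class InsufficientScalesError(HurstFmriError, ValueError):
    """Fewer than three valid window sizes are available for the log-log fit."""


class MissingROIError(HurstFmriError, ValueError):
    """An atlas label has no defined voxels in the map being reduced."""


class ReconciliationError(HurstFmriError, ValueError):
    """Participants table and map collection cannot be matched one-to-one."""


class EmptySelectionWarning(UserWarning):
    """No feature passed the significance filter in a training fold."""


class EmbeddingFallbackWarning(UserWarning):
    """Circulant embedding produced negative eigenvalues; sequential sampler used."""
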