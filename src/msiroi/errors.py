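"""Exception hierarchy shared across the pipeline stages."""


class MsiroiError(Exception):
    """Base class for all package errors."""


class FormatError(MsiroiError):
    """A file could not be parsed as the expected format."""


class ValidationError(MsiroiError):
    """An input violated a documented precondition or invariant."""


class PreprocessingError(MsiroiError):
    """A spectral preprocessing stage produced no usable output."""


class ThresholdingError(PreprocessingError):
    """Automatic thresholding is undefined for this input."""


class PreparationError(MsiroiError):
    """Whole-slide image preparation failed (e.g. no tissue found)."""


class CapabilityError(MsiroiError):
    """A requested optional backend is not available."""


class RegistrationError(MsiroiError):
    """The registration optimizer diverged or its input was degenerate."""


class SelectionError(MsiroiError):
    """Automatic score-map pair selection found no credible match."""


class ClusteringError(MsiroiError):
    """Clustering could not be carried out on this input."""


class CriterionError(MsiroiError):
    """An internal cluster-validity criterion is undefined for this input."""


class QCError(MsiroiError):
    """A quality-control computation received degenerate input."""


class ConfigError(MsiroiError):
    """The run configuration is invalid or refers to missing inputs."""
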