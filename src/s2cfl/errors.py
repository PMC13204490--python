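"""Exception hierarchy used across the pipeline."""


class S2CFLError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(S2CFLError, ValueError):
    """A configuration object violates its invariants."""


class InvalidArgumentError(S2CFLError, ValueError):
    """An argument is outside its documented range."""


class UnsupportedModalityError(S2CFLError, ValueError):
    """Requested modality has no generation/processing kernel."""


class MissingDataError(S2CFLError, ValueError):
    """Missing samples encountered where a complete window is required."""

    def __init__(self, message: str, window_index: int | None = None):
        super().__init__(message)
        self.window_index = window_index


class DegenerateSignalError(S2CFLError, ValueError):
    """Signal has no usable structure (zero variance, no peaks, ...)."""


class EmptyWindowError(S2CFLError, ValueError):
    """Requested episode window lies entirely before the stream start."""


class ShapeError(S2CFLError, ValueError):
    """Array shape incompatible with the configured model."""


class MissingModalityError(S2CFLError, KeyError):
    """A required modality is absent from an episode (no silent imputation)."""


class DataError(S2CFLError, ValueError):
    """Training/evaluation data unusable (empty set, missing labels, ...)."""


class LabelError(S2CFLError, ValueError):
    """Label table incomplete or degenerate (e.g. single-class training set)."""


class ConfigurationError(S2CFLError, ValueError):
    """Inconsistent model/grid/ensemble configuration."""


class UnsupportedModelError(S2CFLError, TypeError):
    """Model type lacks attribution support."""


class DegenerateAttributionError(S2CFLError, ValueError):
    """All attribution mass is zero; ensemble weights undefined."""


class SplitError(S2CFLError, ValueError):
    """Cross-validation split cannot be constructed."""


class DegenerateTestError(S2CFLError, ValueError):
    """Statistical test undefined (e.g. zero-variance paired differences)."""


class DependencyError(S2CFLError, ValueError):
    """A required upstream artifact (checkpoint, stage output) is missing."""
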