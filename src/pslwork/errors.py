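"""Exception hierarchy for the pslwork package."""


class PslworkError(Exception):
    """Base class for all pslwork errors."""


class ValidationError(PslworkError, ValueError):
    """Invalid scalar inputs (sample sizes, SDs, probabilities, counts)."""


class TimingError(ValidationError):
    """Valve-event times are unordered, non-finite or negative."""


class ResolutionError(ValidationError):
    """Requested sampling resolution is too coarse for the computation."""


class DomainError(PslworkError, ValueError):
    """A query time or trace lies outside the domain it must cover."""


class InsufficientDataError(ValidationError):
    """Too few samples for the requested operation."""


class IncompleteSegmentationError(ValidationError):
    """The 17-segment model is not fully populated."""


class CollinearityError(ValidationError):
    """Predictor matrix is rank deficient."""


class ConfigurationError(PslworkError, ValueError):
    """A run configuration is missing required keys or paths."""
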