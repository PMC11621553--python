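"""Exception hierarchy shared across the package."""


class CaspikeError(Exception):
    """Base class for all caspike-specific errors."""


class InvalidParameterError(CaspikeError, ValueError):
    """A simulation or analysis parameter is outside its valid domain."""


class UnsupportedSamplingError(CaspikeError, ValueError):
    """The sampling interval cannot express the +/-10 s and +/-15 s baseline offsets."""


class EmptySeriesError(CaspikeError, ValueError):
    """The trace is too short for any baseline window to exist."""


class UndefinedSNRError(CaspikeError, ArithmeticError):
    """A baseline value of zero makes the relative SNR undefined."""


class UnsupportedBatchError(CaspikeError, ValueError):
    """Traces in a batch disagree on the sampling interval."""


class BoundsError(CaspikeError, IndexError):
    """Slice indices fall outside the stack."""


class DegenerateHistogramError(CaspikeError, ValueError):
    """Automatic thresholding requested on a single-level image."""


class EmptyROIError(CaspikeError, ValueError):
    """Quantification requested on an empty region of interest."""


class ShapeMismatchError(CaspikeError, ValueError):
    """Image and mask shapes disagree."""


class DomainError(CaspikeError, ValueError):
    """A transform was applied outside its mathematical domain."""


class UnsupportedSizeError(CaspikeError, ValueError):
    """Sample size outside the supported range of a test."""


class DegenerateDataError(CaspikeError, ValueError):
    """Data with no variance where variance is required."""


class ConfigError(CaspikeError, ValueError):
    """Invalid or incomplete pipeline configuration."""
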