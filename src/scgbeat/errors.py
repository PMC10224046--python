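"""Exception hierarchy shared by all scgbeat modules."""


class ScgBeatError(Exception):
    """Base class for all scgbeat errors."""


class FormatError(ScgBeatError):
    """A file does not conform to the expected layout (missing columns, channels...)."""


class SamplingError(ScgBeatError):
    """A time axis is not uniformly sampled."""


class ConfigurationError(ScgBeatError):
    """A parameter value violates a precondition (cutoffs, sampling rates, ...)."""


class LengthError(ScgBeatError):
    """A signal is too short for the requested operation."""


class BoundsError(ScgBeatError):
    """A sample/time range falls outside the record."""


class DegenerateTemplateError(ScgBeatError):
    """A template snippet is constant (zero variance) and cannot be matched."""


class InsufficientDataError(ScgBeatError):
    """Too few beats/pairs to perform the requested computation."""


class UndefinedMetricError(ScgBeatError):
    """A metric's denominator is zero."""


class DegenerateDataError(ScgBeatError):
    """Input data has zero variance where variability is required."""
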