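"""Exception hierarchy for the qtcdx pipeline.

Every anticipated failure mode raises a subclass of :class:`QtcdxError`
so callers (and the CLI) can distinguish input problems from analysis
problems without string matching.
"""


class QtcdxError(Exception):
    """Base class for all qtcdx errors."""


class FormatError(QtcdxError):
    """Malformed or unsupported input file."""


class NonUniformSamplingError(FormatError):
    """CSV time column deviates from a uniform grid."""


class UnsupportedRateError(FormatError):
    """Sampling frequency outside the supported 100-2000 Hz range."""


class ParameterError(QtcdxError, ValueError):
    """Invalid parameter set (generator, grading, correction)."""


class InsufficientBeatsError(QtcdxError):
    """Fewer beats than the operation requires."""


class RecordUnevaluableError(QtcdxError):
    """Too few evaluable cardiac cycles to produce a diagnosis."""


class OverlayError(QtcdxError):
    """Cycle overlay could not be built (fewer than two usable beats)."""


class ImmutabilityError(QtcdxError):
    """Attempt to modify a finalized diagnostic report."""


class AlreadyFinalizedError(ImmutabilityError):
    """Report finalized twice."""


class IntegrityError(QtcdxError):
    """Serialized report failed its content-hash verification."""
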