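"""Package-specific exception types."""


class AnimrsaError(Exception):
    """Base class for all errors raised by this package."""


class DesignError(AnimrsaError):
    """The requested experimental design is inconsistent or infeasible."""


class ParameterError(AnimrsaError):
    """A simulation or analysis parameter is outside its valid range."""


class DegenerateDataError(AnimrsaError):
    """A dataset cannot support the requested analysis.

    Raised, e.g., when every trial of some item was rejected for a subject,
    mirroring the exclusion of participants with an empty cell.
    """
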