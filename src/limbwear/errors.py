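"""Exception hierarchy shared across the pipeline."""


class LimbwearError(Exception):
    """Base class for all package errors."""


class FormatError(LimbwearError):
    """A file does not conform to its declared dialect (missing column, bad channel count, ...)."""


class IntegrityError(LimbwearError):
    """Data violate a structural invariant (non-monotone timestamps, epoch seconds not summing to 60, ...)."""


class ConfigError(LimbwearError):
    """A parameter set violates its own invariants."""


class EmptySeriesError(LimbwearError):
    """An operation received a recording or series too short to produce any output."""


class AlignmentError(LimbwearError):
    """Two sensor streams share no overlapping coverage after clock alignment."""


class GenerationError(LimbwearError):
    """A synthetic-cohort configuration is infeasible."""
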