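"""Exception hierarchy shared across the package."""


class MoringaQCError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MoringaQCError):
    """A table is missing required columns or has a malformed layout."""


class ValidationError(MoringaQCError):
    """A value violates a domain constraint (negative response, bad slope, ...)."""


class InsufficientDataError(MoringaQCError):
    """Not enough rows/levels/replicates to compute the requested statistic."""


class DegenerateDesignError(MoringaQCError):
    """The design matrix carries no information (e.g. a single distinct level)."""


class InvalidCurveError(MoringaQCError):
    """A calibration curve cannot be used (non-positive or zero slope, missing limits)."""


class FixtureLookupError(MoringaQCError, KeyError):
    """Unknown bundled-fixture name."""
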