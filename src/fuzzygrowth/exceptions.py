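"""Exception hierarchy shared across the pipeline stages."""


class FuzzyGrowthError(Exception):
    """Base class for all package errors."""


class ConfigError(FuzzyGrowthError, ValueError):
    """A configuration value violates its contract; names the field."""


class MissingCellError(FuzzyGrowthError, KeyError):
    """A design cell required by a stage has no records."""


class DegenerateDataError(FuzzyGrowthError, ValueError):
    """Data carry no usable variation (constant vector, zero residuals)."""


class DefuzzificationError(FuzzyGrowthError, ValueError):
    """Aggregated membership is zero everywhere; no centroid exists."""
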