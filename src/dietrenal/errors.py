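"""Exception hierarchy shared across the package."""


class DietRenalError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DietRenalError):
    """An invalid configuration value; the message names the offending field."""


class MissingDataError(DietRenalError):
    """A required input value is absent; the message identifies it."""


class SchemaError(DietRenalError):
    """An input table lacks required columns or has the wrong layout."""


class EstimationError(DietRenalError):
    """A regression model could not be estimated (singular design, too few clusters, ...)."""


class SeparationError(EstimationError):
    """A logistic model has an exposure category with zero (or all) events."""
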