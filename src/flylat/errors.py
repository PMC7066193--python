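"""Exception types shared across the package."""


class FlylatError(Exception):
    """Base class for package errors."""


class SchemaError(FlylatError):
    """An input table is missing a required column or has a bad dtype."""


class DataError(FlylatError):
    """An input table violates a data invariant (named row/fly in message)."""


class ConsistencyError(FlylatError):
    """Experiment metadata is internally inconsistent (partner links, sex/context)."""


class InsufficientDataError(FlylatError):
    """A statistic was requested on too few observations."""


class DegenerateSampleError(FlylatError):
    """A statistic is undefined because the sample has zero variance."""


class AliasingError(FlylatError):
    """A requested ANOVA term is inestimable because of empty design cells."""


class ConfigError(FlylatError):
    """A configuration value is invalid."""
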