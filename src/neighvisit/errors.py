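"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`NeighvisitError` so drivers can halt
with a stage name and a machine-readable cause instead of a bare traceback.
"""


class NeighvisitError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(NeighvisitError, ValueError):
    """A configuration value violates its contract."""


class InvalidRecordError(NeighvisitError, ValueError):
    """A visit record violates the censoring/imputation contract."""


class SchemaError(NeighvisitError, ValueError):
    """An input table is missing a required column."""


class ReferentialIntegrityError(NeighvisitError, ValueError):
    """A visit record references a tract or POI id that does not resolve."""


class DegenerateInputError(NeighvisitError, ValueError):
    """A statistic was requested on constant or otherwise degenerate data."""


class SingularDesignError(NeighvisitError, ValueError):
    """The design matrix is rank deficient where a unique fit is required."""


class UnderdeterminedDesignError(NeighvisitError, ValueError):
    """Fewer observations than variables."""


class ExhaustionError(NeighvisitError, RuntimeError):
    """An elimination cascade would remove every variable."""


class SampleSizeError(NeighvisitError, ValueError):
    """Too few observations to train the requested model."""


class EmptyAnalysisError(NeighvisitError, ValueError):
    """Tract filtering removed every row."""
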