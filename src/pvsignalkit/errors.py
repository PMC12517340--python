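"""Exception hierarchy for pvsignalkit."""


class PvSignalError(Exception):
    """Base class for all pvsignalkit errors."""


class SchemaError(PvSignalError):
    """An input table is missing a mandatory column or is otherwise malformed."""


class EmptyDatabaseError(PvSignalError):
    """The demographics table contains no usable reports."""


class ConfigurationError(PvSignalError):
    """An unknown policy, stratum, or invalid configuration value."""


class UndefinedRorError(PvSignalError):
    """A zero off-diagonal cell makes the ROR undefined without continuity correction."""


class UndefinedCiError(PvSignalError):
    """A zero cell makes the Wald confidence interval undefined without correction."""


class ContractError(PvSignalError):
    """An operation was called outside its contract (e.g. Fisher on non-integer cells)."""


class InvalidMeasureError(PvSignalError):
    """A nonpositive height or weight was supplied to a BMI computation."""


class InsufficientDataError(PvSignalError):
    """Too few observations for the requested fit or summary."""


class DegenerateDataError(PvSignalError):
    """All observations identical; the Weibull MLE diverges."""
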