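"""Exception types shared across the package."""


class CladecalError(Exception):
    """Base class for all package errors."""


class InvalidRateError(CladecalError, ValueError):
    """A diversification or sampling rate is outside its valid domain."""


class InvalidTreeError(CladecalError, ValueError):
    """A tree violates rootedness, binarity, ultrametricity or age ordering."""


class InvalidGridError(CladecalError, ValueError):
    """A density evaluation grid is empty or lies below the fossil age."""


class InvalidWeightsError(CladecalError, ValueError):
    """Fossil weights do not form a probability vector."""


class ConstraintMappingError(CladecalError, ValueError):
    """A clade constraint's tip set does not map to a monophyletic node."""


class TaxonMappingError(CladecalError, ValueError):
    """Alignment taxa cannot be matched to tree tips."""


class SchemaError(CladecalError, ValueError):
    """A tabular input is missing required columns."""


class SurvivalError(CladecalError, RuntimeError):
    """Rejection sampling failed to produce a surviving lineage history."""
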