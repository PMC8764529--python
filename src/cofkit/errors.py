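"""Exception hierarchy shared across cofkit modules.

All errors derive from :class:`CofkitError` (itself a ``ValueError``) so
callers can catch either the package-wide base or the builtin.
"""


class CofkitError(ValueError):
    """Base class for all cofkit errors."""


class PDBParseError(CofkitError):
    """A fixed-column coordinate record could not be parsed."""


class EmptyStructureError(CofkitError):
    """No ATOM/HETATM records found where at least one is required."""


class SerializationError(CofkitError):
    """A model cannot be written in the requested format."""


class DegenerateGeometryError(CofkitError):
    """Collinear/duplicate points or an on-axis reference atom."""


class SelectorError(CofkitError):
    """A chain/residue/atom selector matched nothing."""


class InsufficientPointsError(CofkitError):
    """Fewer points than the operation mathematically requires."""


class SchemaError(CofkitError):
    """Tabular input is missing required columns."""


class ValidationError(CofkitError):
    """Input values violate a documented invariant."""


class IntegrationError(CofkitError):
    """Too few points inside the integration window."""


class NormalizationError(CofkitError):
    """Zero denominator while normalizing peak areas."""


class FitError(CofkitError):
    """A regression or model fit could not be performed."""


class UndefinedProfileError(CofkitError):
    """All formation rates of a replicate are zero."""


class SpecError(CofkitError):
    """A synthetic-data specification is internally infeasible."""
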