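"""Exception hierarchy for cfrisk.

All package errors derive from :class:`CfriskError` so callers can catch
broadly; the subclasses mirror the failure modes of the estimation
pipeline (bad input schema, incomplete data, empty conditioning cells,
use-before-fit).
"""


class CfriskError(Exception):
    """Base class for all cfrisk errors."""


class SchemaError(CfriskError, ValueError):
    """A required column is missing or inputs do not match a fitted model."""


class CompletenessError(CfriskError, ValueError):
    """Missing values found; cfrisk enforces a complete-case contract."""


class DomainError(CfriskError, ValueError):
    """A value is outside its allowed domain (e.g. non-binary treatment)."""


class EstimabilityError(CfriskError, RuntimeError):
    """A conditioning cell required by the requested analysis is empty or
    degenerate (e.g. a single treatment level in a stratum, zero weight sum)."""


class StateError(CfriskError, RuntimeError):
    """An object was used before it was fitted."""
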