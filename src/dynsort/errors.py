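"""Exception hierarchy.

All package errors derive from :class:`DynsortError` so callers can catch one
base class; most also derive from the matching builtin (ValueError/KeyError)
to behave idiomatically.
"""


class DynsortError(Exception):
    """Base class for all dynsort errors."""


class InvalidArgumentError(DynsortError, ValueError):
    """An argument violates a documented precondition."""


class ShapeError(DynsortError, ValueError):
    """Array dimensions are inconsistent."""


class LookupError_(DynsortError, KeyError):
    """An id (electrode, amplitude, neuron) is unknown."""


class EmptySelectionError(DynsortError, ValueError):
    """An electrode-selection rule returned no electrodes."""


class RankDeficiencyError(DynsortError, ValueError):
    """A least-squares problem is rank deficient at ridge = 0."""


class TemplateDesignError(DynsortError, ValueError):
    """An input template cannot be placed on the given trace."""


class InsufficientDataError(DynsortError, ValueError):
    """Too few samples or trials for identification."""


class IdentifiabilityError(DynsortError, ValueError):
    """The window operator loses column rank; inputs are not identifiable."""


class SizeError(DynsortError, ValueError):
    """An exhaustive search space is too large."""


class DataError(DynsortError, ValueError):
    """Measurements contain non-finite values."""
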