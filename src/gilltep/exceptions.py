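"""Exception hierarchy.

Every error raised by this package derives from :class:`GillTepError`, so
callers can catch the whole family with one clause.  Errors that signal a
bad *value* (rather than a bad model or design) also derive from
:class:`ValueError` for ergonomic use with plain ``except ValueError``.
"""


class GillTepError(Exception):
    """Base class for all package errors."""


class InvalidInputError(GillTepError, ValueError):
    """A numeric argument violates a precondition (non-positive, non-finite...)."""


class ConfigurationError(GillTepError, ValueError):
    """A configuration table or mapping is missing a required entry."""


class UnsupportedModelError(GillTepError):
    """The requested computation lies outside the model's validity domain."""


class InfeasiblePotentialError(GillTepError, ValueError):
    """No positive permeability ratio can reproduce the requested potential."""


class DegenerateSolutionError(GillTepError):
    """The inverse problem is under-determined (any ratio fits)."""


class NegativeInfluxError(InvalidInputError):
    """Water radioactivity rose during the flux period."""


class PositiveEffluxError(InvalidInputError):
    """Computed unidirectional efflux came out positive."""


class UndefinedQ10Error(InvalidInputError):
    """Q10 is undefined for rates of opposite sign or zero."""


class DepletionError(GillTepError):
    """The simulated water Na pool was driven to zero."""


class IncompleteDesignError(GillTepError, ValueError):
    """A repeated-measures table has missing or duplicated fish x condition cells."""


class DegenerateVarianceError(GillTepError, ValueError):
    """All paired differences are identical; the t statistic is undefined."""
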