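"""Exception hierarchy for the pipeline.

All errors derive from :class:`DegnetError` so callers can catch the whole
family; most also derive from :class:`ValueError` because they signal invalid
user input rather than internal failure.
"""


class DegnetError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(DegnetError, ValueError):
    """The study design cannot support the requested operation."""


class ParameterError(DegnetError, ValueError):
    """A numeric parameter is out of its valid domain."""


class FormatError(DegnetError, ValueError):
    """A file does not conform to its expected format."""


class ParseError(FormatError):
    """A cell or token could not be parsed; carries coordinates when known."""


class DomainError(DegnetError, ValueError):
    """An operation was applied to data outside its mathematical domain."""


class CalibrationError(DegnetError, ValueError):
    """The empirical null cannot be fitted from the available permutations."""


class DegenerateVarianceError(DegnetError, ArithmeticError):
    """Zero pooled variance with unequal group means: the T statistic diverges."""
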