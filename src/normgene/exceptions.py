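"""Exception hierarchy for normgene.

All errors raised on invalid scientific input derive from
:class:`NormgeneError` so callers can catch the package's failures with a
single except clause while still distinguishing the cause.
"""


class NormgeneError(Exception):
    """Base class for all normgene errors."""


class DuplicateIdentifierError(NormgeneError, ValueError):
    """An identifier (gene or sample) occurs more than once."""


class MatrixParseError(NormgeneError, ValueError):
    """A cell of an input table could not be parsed; message carries the location."""


class ShapeError(NormgeneError, ValueError):
    """Input has the wrong dimensions (e.g. fewer than 3 samples)."""


class UndefinedStatisticError(NormgeneError, ValueError):
    """A statistic is undefined for this input (e.g. CV with non-positive mean)."""


class InsufficientDataError(NormgeneError, ValueError):
    """Not enough observations to compute the requested quantity."""


class ParameterError(NormgeneError, ValueError):
    """A user-supplied parameter is outside its domain (e.g. k > n, slope >= 0)."""


class DegenerateInputError(NormgeneError, ValueError):
    """Input is degenerate for the requested test (e.g. zero variance)."""


class ConfigurationError(NormgeneError, ValueError):
    """A configuration is inconsistent or incomplete (e.g. gene without NTC)."""


class InputMismatchError(NormgeneError, ValueError):
    """Two inputs that must agree do not (e.g. rankings over different gene sets)."""
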