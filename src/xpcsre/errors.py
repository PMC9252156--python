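"""Exception hierarchy.

The CLI maps these onto exit codes: configuration problems -> 2,
data/format problems -> 3, numeric failures -> 4.
"""


class XpcsreError(Exception):
    """Base class for all package errors."""


class ParameterError(XpcsreError, ValueError):
    """An argument or configuration field is invalid; message names the field."""


class ConfigError(ParameterError):
    """A pipeline configuration file is structurally invalid."""


class FormatError(XpcsreError, OSError):
    """An on-disk artefact does not match the documented schema."""


class NumericalInstabilityError(XpcsreError, ArithmeticError):
    """Integration produced non-finite values (typically dt too large)."""


class PlacementError(XpcsreError, RuntimeError):
    """Random particle placement with minimum separation exhausted its attempt budget."""


class EmptyRingError(XpcsreError, ValueError):
    """A q-ring selection contains no detector pixels."""


class OutOfWindowError(XpcsreError, RuntimeError):
    """The intensity peak sits on (or beyond) the edge of the q window,
    so the peak position — and hence the characteristic length — is undefined."""


class NoDecayError(XpcsreError, RuntimeError):
    """A correlation cut never decays below the threshold (frozen dynamics)."""


class InsufficientPeaksError(XpcsreError, RuntimeError):
    """Fewer than two contrast maxima: spacing statistics are undefined."""
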