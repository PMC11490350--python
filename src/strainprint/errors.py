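"""Exception hierarchy for the strainprint pipeline.

All errors derive from :class:`StrainprintError` so callers can catch the
package's failures with a single except clause while still distinguishing
configuration mistakes from numerical blow-ups or data problems.
"""


class StrainprintError(Exception):
    """Base class for all strainprint errors."""


class ConfigurationError(StrainprintError, ValueError):
    """Invalid model/run configuration (bad timing markers, steps, ...)."""


class DomainError(StrainprintError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class NumericalError(StrainprintError, ArithmeticError):
    """The integrator produced non-finite state; carries diagnostics."""


class AlignmentError(StrainprintError, ValueError):
    """Two time series do not share a sampling grid; resample first."""


class EmptyFingerprintError(StrainprintError, ValueError):
    """A data fingerprint has no cohort members; raise threshold or check data."""


class ParseError(StrainprintError, ValueError):
    """A strain CSV or config file failed validation."""
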