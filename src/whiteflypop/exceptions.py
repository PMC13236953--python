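"""Exception hierarchy for whiteflypop.

Everything derives from :class:`WhiteflyPopError` so callers can catch the
package's errors with a single except clause; the concrete classes also
derive from :class:`ValueError` because they all signal invalid inputs.
"""


class WhiteflyPopError(Exception):
    """Base class for all whiteflypop errors."""


class ConfigurationError(WhiteflyPopError, ValueError):
    """Invalid synthetic-data or model configuration."""


class DomainError(WhiteflyPopError, ValueError):
    """An argument lies outside its mathematical domain."""


class InconsistentLifeTableError(DomainError):
    """A life table implies daily probabilities that cannot sum to one."""


class DegenerateRatesError(DomainError):
    """Daily rates are degenerate (e.g. r + d = 0, or r = 0 where 1/r is needed)."""


class InfeasibleTargetError(WhiteflyPopError, ValueError):
    """A calibration target cannot be reached from the given rates."""


class InfeasibleCalibrationError(InfeasibleTargetError):
    """Density-dependence calibration is impossible (population does not grow)."""


class InputLengthError(WhiteflyPopError, ValueError):
    """An input series is too short for the requested computation."""


class AlphabetError(WhiteflyPopError, ValueError):
    """A sequence contains characters outside the A/C/G/T/N alphabet."""
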