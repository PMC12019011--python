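"""Exception hierarchy for the toolkit.

All toolkit errors derive from :class:`GvstimError` so callers can catch
one base class; subclasses distinguish validation problems (bad arguments
or configuration), safety-limit violations, and data-format problems.
"""


class GvstimError(Exception):
    """Base class for all toolkit errors."""


class DomainError(GvstimError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigError(GvstimError, ValueError):
    """A configuration value is invalid or inconsistent."""


class NyquistError(ConfigError):
    """A requested bandwidth or frequency violates the Nyquist criterion."""


class SafetyError(GvstimError, ValueError):
    """A command or trace exceeds the configured current safety limit."""


class CalibrationError(GvstimError, ValueError):
    """An offset-calibration value is outside the plausible range."""


class DataFormatError(GvstimError, ValueError):
    """An input file does not parse under the declared dialect."""


class StaircaseStateError(GvstimError, RuntimeError):
    """An update was applied to a finished (or otherwise invalid) staircase."""


class RunawayError(GvstimError, RuntimeError):
    """An adaptive session failed to terminate within its trial cap."""


class InsufficientDataError(GvstimError, ValueError):
    """Not enough data to compute the requested estimate."""
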