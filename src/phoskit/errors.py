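"""Exception and warning hierarchy shared by all phoskit modules."""


class PhoskitError(Exception):
    """Base class for all phoskit errors."""


class DomainError(PhoskitError, ValueError):
    """An input is outside the physically/chemically supported range."""


class InconsistentChemistryError(PhoskitError, ValueError):
    """Alkalinity bookkeeping produced a non-physical result (e.g. A_c <= 0)."""


class BracketError(PhoskitError, ValueError):
    """A root solve could not bracket the requested target."""


class InsufficientDataError(PhoskitError, ValueError):
    """Too few data points to perform the requested fit or estimate."""


class CalibrationError(PhoskitError, ValueError):
    """A sensor calibration failed its quality gate or is degenerate."""


class FitError(PhoskitError, RuntimeError):
    """A nonlinear fit failed to converge after multistart."""


class SchemaError(PhoskitError, ValueError):
    """An input file is missing required columns or has malformed rows."""


class ProtocolError(PhoskitError, ValueError):
    """A trace does not follow the expected light/dark measurement protocol."""


class ConfigError(PhoskitError, ValueError):
    """A run configuration value is missing or inconsistent."""


class UndefinedStatisticError(PhoskitError, ZeroDivisionError):
    """A statistic is undefined for the given sample (e.g. zero variance)."""


class PhoskitWarning(UserWarning):
    """Base class for phoskit warnings."""


class SuspectCalibrationWarning(PhoskitWarning):
    """A calibration offset is unusually large but the result is still computed."""


class PoorLinearityWarning(PhoskitWarning):
    """A linear fit's r-squared fell below its quality threshold."""


class ExtrapolationWarning(PhoskitWarning):
    """A fitted curve was evaluated outside the data range."""


class AttenuationWarning(PhoskitWarning):
    """Culture optical density exceeds the PAR self-shading ceiling."""


class DataGapWarning(PhoskitWarning):
    """A time series contains gaps larger than the nominal sampling interval."""


class SanityFlagWarning(PhoskitWarning):
    """A derived quantity violates a physical plausibility bound."""
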