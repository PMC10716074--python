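"""Exception hierarchy for rrsim."""


class RRSimError(Exception):
    """Base class for all rrsim errors."""


class ConfigurationError(RRSimError):
    """A configuration value is inconsistent or infeasible."""


class GenerationError(RRSimError):
    """Stochastic data generation failed to satisfy its contract."""


class CalibrationError(RRSimError):
    """Trait calibration is impossible (e.g. zero genetic variance)."""


class FittingError(RRSimError):
    """A statistical model could not be fitted."""
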