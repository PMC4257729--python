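"""Exception types raised across the package."""


class GrowthSimError(Exception):
    """Base class for all package-specific errors."""


class CurveFormatError(GrowthSimError, ValueError):
    """A reference-curve table is malformed (missing columns, bad ages, empty)."""


class AgeSpanError(GrowthSimError, ValueError):
    """A curve was evaluated outside its tabulated age span.

    Extrapolation is deliberately forbidden: silently clamping reference
    curves hides configuration errors in life-span simulations.
    """


class ParameterError(GrowthSimError, ValueError):
    """Invalid parameter value (non-positive factor, adult height below birth height, ...)."""


class CompositionError(GrowthSimError, ValueError):
    """Body-composition bookkeeping became inconsistent (e.g. FMI* >= BMI,
    organ masses exceeding fat-free mass)."""


class CalibrationError(GrowthSimError, RuntimeError):
    """A calibration target could not be bracketed or reached."""


class ConfigError(GrowthSimError, ValueError):
    """Run configuration failed validation; message carries the offending key path."""


class StarvationCollapse(GrowthSimError, RuntimeError):
    """Essential stores fell below the survival floor; the simulation cannot continue.

    The model does not represent death; this signal marks the state where
    continued integration would drive masses to unphysical values.
    """

    def __init__(self, message: str, age_days: float | None = None):
        super().__init__(message)
        self.age_days = age_days
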