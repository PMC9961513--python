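"""Exception hierarchy shared across the package."""


class SeedHSIError(Exception):
    """Base class for all package errors."""


class InputError(SeedHSIError, ValueError):
    """Invalid argument values or incompatible shapes."""


class FormatError(SeedHSIError, ValueError):
    """Malformed file content (headers, band counts, label columns)."""


class CalibrationError(SeedHSIError, ValueError):
    """Reflectance calibration impossible at one or more positions."""


class UndefinedMetricError(SeedHSIError, ValueError):
    """A metric's denominator is zero for the given counts."""


class DegenerateFitError(SeedHSIError, RuntimeError):
    """A fitted quantity collapsed (zero variance, vanishing multiplier, rank)."""
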