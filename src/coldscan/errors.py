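"""Exception hierarchy shared across the package."""


class ColdscanError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ColdscanError, ValueError):
    """Invalid simulation or pipeline configuration."""


class UndefinedSignalError(ColdscanError):
    """Both intensity channels are zero: the oxidation level is undefined."""


class UndefinedControlError(ColdscanError):
    """The control-condition denominator is zero."""


class DegenerateFitError(ColdscanError):
    """A fit cannot be performed (flat signal, collinear data, <2 points...)."""


class UndefinedResultError(ColdscanError):
    """A statistic is requested on an empty filtered set."""
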