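"""Exception hierarchy shared across the package."""


class SpmsCeaError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SpmsCeaError, ValueError):
    """A scalar model parameter is outside its admissible range."""


class InvalidMatrixError(SpmsCeaError, ValueError):
    """A transition matrix violates row-stochasticity or bounds."""


class OutOfRangeError(SpmsCeaError, ValueError):
    """An age lookup fell outside the life-table range."""


class ConfigError(SpmsCeaError, ValueError):
    """A configuration file or parameter bundle failed validation."""
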