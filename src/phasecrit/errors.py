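"""Exception hierarchy shared across the package."""


class PhasecritError(Exception):
    """Base class for all package errors."""


class DegenerateSignalError(PhasecritError):
    """Signal has no usable oscillatory content (constant or all-zero)."""


class ShapeError(PhasecritError):
    """Inputs disagree in length or sampling rate."""


class ParameterError(PhasecritError):
    """A configuration value is outside its admissible range."""


class SeriesTooShortError(PhasecritError):
    """Series too short to support the requested window scheme."""


class DegeneratePlotError(PhasecritError):
    """Fluctuation plot contains zero fluctuations; no exponent is defined."""


class RandomizationError(PhasecritError):
    """Weight-preserving rewiring ran out of restarts."""
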