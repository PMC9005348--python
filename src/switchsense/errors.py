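"""Exception hierarchy shared across the package."""


class SwitchSenseError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SwitchSenseError, ValueError):
    """A model parameter is outside its physical domain."""


class ScheduleError(SwitchSenseError, ValueError):
    """An illumination schedule is empty or inconsistent."""


class InsufficientDataError(SwitchSenseError, ValueError):
    """Too few samples/cycles for the requested analysis."""


class AlignmentError(SwitchSenseError, ValueError):
    """Traces passed to a global fit do not share a time base."""


class LayoutError(SwitchSenseError, ValueError):
    """A phantom layout is geometrically invalid (outside image, overlap)."""


class FitError(SwitchSenseError, RuntimeError):
    """A fit that must succeed (e.g. the reference offset) failed."""


class UnidentifiableError(FitError):
    """The data contain no transition; the model parameters are not identifiable."""


class RangeError(SwitchSenseError, ValueError):
    """Input values do not span the range required by the fit."""


class ConfigurationError(SwitchSenseError, ValueError):
    """Invalid combination of configuration options."""


class ValidationError(SwitchSenseError, ValueError):
    """Stored data and metadata disagree."""
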