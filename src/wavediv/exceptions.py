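"""Exception types shared across the package."""


class WavedivError(Exception):
    """Base class for package-specific errors."""


class DimensionError(WavedivError, ValueError):
    """An array has the wrong shape or side length."""


class ValidationError(WavedivError, ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(WavedivError, ValueError):
    """A model, reference or option is missing or inconsistent."""


class EstimationError(WavedivError, ValueError):
    """A distribution or rate cannot be estimated from the given data."""


class AlignmentError(WavedivError, ValueError):
    """Predictions and truth records cannot be matched one-to-one."""
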